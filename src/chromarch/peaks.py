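"""ChIP-peak annotation relative to genes and enrichment around TAD
boundaries.

Peaks are anchored at their narrowPeak summit (midpoint when the summit
offset is -1). TSS distance is signed by gene strand: negative = upstream of
the gene. Distance classes default to promoter <= 2 kb, proximal <= 10 kb,
distal beyond; both cutoffs are exposed as parameters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io as cio
from .intervals import nearest_point, overlaps_any, overlap_flags_df
from .tads import TadSet

log = logging.getLogger("chromarch")


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                   promoter_bp: int = 2_000,
                   proximal_bp: int = 10_000) -> tuple[pd.DataFrame, dict]:
    """Per-peak nearest-TSS class and genome-wide class fractions.

    Ties between equidistant TSSs break toward the smaller coordinate.
    Peaks on chromosomes absent from the gene model are classed distal with
    a warning."""
    if genes.empty:
        raise ValueError("gene model is empty")
    summits = cio.peak_summits(peaks) if len(peaks) else np.array([], np.int64)
    tss = cio.gene_tss(genes)
    strand = genes["strand"].to_numpy()
    gchrom = genes["chrom"].to_numpy()
    dist = np.full(len(peaks), np.nan)
    klass = np.full(len(peaks), "distal", dtype=object)
    for c in pd.unique(peaks["chrom"]) if len(peaks) else []:
        psel = np.flatnonzero(peaks["chrom"].to_numpy() == c)
        gsel = gchrom == c
        if not gsel.any():
            log.warning("chromosome %s absent from gene model; peaks classed distal", c)
            continue
        idx, d = nearest_point(summits[psel], tss[gsel])
        sgn = np.where(strand[gsel][idx] == "+", 1.0, -1.0)
        dist[psel] = d * sgn
        ad = np.abs(d)
        klass[psel] = np.where(ad <= promoter_bp, "promoter",
                               np.where(ad <= proximal_bp, "proximal", "distal"))
    table = peaks.copy()
    table["tss_distance"] = dist
    table["class"] = klass
    n = len(table)
    fractions = {k: (float((klass == k).sum()) / n if n else 0.0)
                 for k in ("promoter", "proximal", "distal")}
    return table, fractions


def boundary_enrichment_profile(peaks: pd.DataFrame, tads: TadSet,
                                chromsizes: dict[str, int],
                                span_bp: int = 500_000,
                                step_bp: int = 25_000) -> tuple[np.ndarray, np.ndarray]:
    """Peak-summit counts per step-bin across +-span around each boundary
    midpoint, normalized per boundary (counts / boundaries used).

    Boundaries truncated by a chromosome edge are excluded. Returns
    (profile, bin_offsets) with len(profile) = 2 * span / step."""
    bnd = tads.boundary_regions()
    if bnd.empty:
        raise ValueError("no boundaries to profile")
    nb = 2 * span_bp // step_bp
    offsets = np.arange(-span_bp, span_bp, step_bp)
    summits = cio.peak_summits(peaks) if len(peaks) else np.array([], np.int64)
    counts = np.zeros(nb)
    used = 0
    for _, r in bnd.iterrows():
        mid = (r["start"] + r["end"]) // 2
        if mid - span_bp < 0 or mid + span_bp > chromsizes[r["chrom"]]:
            continue
        used += 1
        sel = peaks["chrom"].to_numpy() == r["chrom"] if len(peaks) else np.array([], bool)
        s = summits[sel]
        rel = s - mid
        ok = (rel >= -span_bp) & (rel < span_bp)
        if ok.any():
            b = ((rel[ok] + span_bp) // step_bp).astype(int)
            np.add.at(counts, b, 1.0)
    if used == 0:
        raise ValueError("all boundaries truncated by chromosome edges")
    return counts / used, offsets


def peaks_at_boundaries(peaks: pd.DataFrame, tads: TadSet) -> dict:
    """Fraction of peaks overlapping boundary regions, and fraction of
    boundaries bound by >= 1 peak (>= 1 bp rule both directions)."""
    bnd = tads.boundary_regions()
    if len(peaks) == 0 or bnd.empty:
        return {"peaks_total": int(len(peaks)), "boundaries_total": int(len(bnd)),
                "peaks_at_boundaries": 0, "boundaries_bound": 0,
                "peak_fraction": 0.0, "boundary_fraction": 0.0}
    p_hit = overlap_flags_df(peaks, bnd)
    b_hit = overlap_flags_df(bnd, peaks)
    return {"peaks_total": int(len(peaks)),
            "boundaries_total": int(len(bnd)),
            "peaks_at_boundaries": int(p_hit.sum()),
            "boundaries_bound": int(b_hit.sum()),
            "peak_fraction": float(p_hit.sum()) / len(peaks),
            "boundary_fraction": float(b_hit.sum()) / len(bnd)}


def signal_heatmap_matrix(track: pd.DataFrame, anchors: pd.DataFrame,
                          span_bp: int, step_bp: int) -> np.ndarray:
    """anchors x bins matrix of mean bedGraph signal per step-bin over
    +-span around each anchor midpoint; row order preserved.

    ``track`` is a bedGraph frame (chrom, start, end, value); signal is
    treated as a per-bp density constant over each record."""
    if anchors.empty:
        raise ValueError("anchors are empty")
    nb = 2 * span_bp // step_bp
    out = np.zeros((len(anchors), nb))
    tr_by_chrom = {c: g.sort_values("start") for c, g in track.groupby("chrom", sort=False)}
    missing = set(anchors["chrom"]) - set(tr_by_chrom)
    if missing:
        raise ValueError(f"track has no records for anchor chromosomes {sorted(missing)}")
    cums = {}
    for c, g in tr_by_chrom.items():
        edges = np.concatenate([g["start"].to_numpy(), [g["end"].to_numpy()[-1]]])
        vals = g["value"].to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(vals * (g["end"] - g["start"]).to_numpy())])
        cums[c] = (edges.astype(float), cum)
    for k, (_, r) in enumerate(anchors.iterrows()):
        mid = (r["start"] + r["end"]) // 2
        edges, cum = cums[r["chrom"]]
        bb = np.linspace(mid - span_bp, mid + span_bp, nb + 1)
        ib = np.interp(bb, edges, cum)
        out[k] = (ib[1:] - ib[:-1]) / step_bp
    return out
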