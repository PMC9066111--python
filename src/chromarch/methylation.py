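"""MeDIP window-count analysis: metagene profiles over gene bodies, DMR
calling by windowed exact binomial testing, and genomic-feature annotation.

MeDIP is enrichment-based, so methylation is modeled as window counts rather
than CpG-level calls: fixed-width windows (default 1 kb) per condition and
replicate. DMRs are merged runs of significant windows sharing a direction;
hyper/hypo is relative to the treated condition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome_sim import MethylationTrack
from . import io as cio
from .stats import binom_test_two_sided, bh_adjust
from .intervals import overlap_flags_df

log = logging.getLogger("chromarch")

N_FLANK_BINS = 50
N_BODY_BINS = 100
N_PROFILE_BINS = 2 * N_FLANK_BINS + N_BODY_BINS   # fixed at 200


def _normalized_signal(track: MethylationTrack, condition: str) -> np.ndarray:
    """Mean counts-per-million over replicates (global window array)."""
    arrs = []
    for rep, counts in enumerate(track.counts[condition]):
        lib = track.library_size(condition, rep)
        arrs.append(counts / lib * 1e6)
    return np.mean(arrs, axis=0)


def metagene_profile(track: MethylationTrack, genes: pd.DataFrame,
                     condition: str = "control",
                     flank_bp: int = 2_000) -> np.ndarray:
    """Strand-aware mean signal profile: 50 upstream-flank bins, 100 scaled
    gene-body bins, 50 downstream-flank bins (200 total).

    Signal is library-size normalized and averaged over replicates, then the
    per-bp density is integrated exactly over each profile bin via the
    cumulative integral of the window track. Genes shorter than 100 bp are
    skipped."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    sig = _normalized_signal(track, condition)
    win = track.windows.resolution
    # cumulative integral of per-bp density per chromosome
    cums = {}
    for c in track.windows.chroms:
        o, n = track.windows.offsets[c], track.windows.n_bins[c]
        dens = sig[o:o + n] / win
        cums[c] = (np.concatenate([[0.0], np.cumsum(dens)]) * win,
                   track.windows.chromsizes[c])

    profiles = []
    skipped = 0
    for _, g in genes.iterrows():
        glen = g["end"] - g["start"]
        if glen < 100:
            skipped += 1
            continue
        c = g["chrom"]
        if c not in cums:
            continue
        cum, clen = cums[c]

        def integral(a, b):
            a = np.clip(a, 0, clen)
            b = np.clip(b, 0, clen)
            ia = np.interp(a, np.arange(len(cum)) * win, cum)
            ib = np.interp(b, np.arange(len(cum)) * win, cum)
            return ib - ia

        # 5'->3' edge coordinates of the 200 profile bins
        if g["strand"] == "+":
            edges = np.concatenate([
                np.linspace(g["start"] - flank_bp, g["start"], N_FLANK_BINS + 1)[:-1],
                np.linspace(g["start"], g["end"], N_BODY_BINS + 1)[:-1],
                np.linspace(g["end"], g["end"] + flank_bp, N_FLANK_BINS + 1)])
        else:
            edges = np.concatenate([
                np.linspace(g["end"] + flank_bp, g["end"], N_FLANK_BINS + 1)[:-1],
                np.linspace(g["end"], g["start"], N_BODY_BINS + 1)[:-1],
                np.linspace(g["start"], g["start"] - flank_bp, N_FLANK_BINS + 1)])
        a = np.minimum(edges[:-1], edges[1:])
        b = np.maximum(edges[:-1], edges[1:])
        width = b - a
        with np.errstate(invalid="ignore"):
            vals = np.where(width > 0, integral(a, b) / np.maximum(width, 1e-12), 0.0)
        profiles.append(vals)
    if skipped:
        log.info("metagene: %d genes shorter than 100 bp skipped", skipped)
    if not profiles:
        raise ValueError("no usable genes for metagene profile")
    return np.mean(profiles, axis=0)


def call_dmrs(track: MethylationTrack, fdr: float = 0.05, lfc: float = 1.0,
              merge_gap: int = 1_000, min_count: int = 10) -> pd.DataFrame:
    """Windowed DMR calling.

    Per window: exact binomial test of pooled treated counts against pooled
    total with the library-size null (same engine as the differential-
    interaction caller); BH over tested windows; windows at q < fdr and
    |log2FC| > lfc merged when within merge_gap and of the same direction.

    Returns chrom, start, end, direction, log2fc (from region-summed
    counts), q_min, n_windows."""
    xt = np.sum(track.counts["treated"], axis=0)
    xc = np.sum(track.counts["control"], axis=0)
    s_t, s_c = float(xt.sum()), float(xc.sum())
    keep = (xt + xc) >= min_count
    if not keep.any():
        log.warning("call_dmrs: no testable windows")
        return pd.DataFrame(columns=["chrom", "start", "end", "direction",
                                     "log2fc", "q_min", "n_windows"])
    p0 = s_t / (s_t + s_c)
    p = binom_test_two_sided(xt[keep], (xt + xc)[keep], p0)
    q = np.full(len(xt), np.nan)
    q[keep] = bh_adjust(p)
    lfc_all = np.log2(((xt + 0.5) / s_t) / ((xc + 0.5) / s_c))
    sig = keep & (q < fdr) & (np.abs(lfc_all) > lfc)

    wf = track.window_frame()
    rows = []
    for c in track.windows.chroms:
        o, n = track.windows.offsets[c], track.windows.n_bins[c]
        idx = np.flatnonzero(sig[o:o + n])
        if len(idx) == 0:
            continue
        starts = wf["start"].to_numpy()[o:o + n]
        ends = wf["end"].to_numpy()[o:o + n]
        direction = np.where(lfc_all[o:o + n] > 0, "hyper", "hypo")
        cur = [idx[0]]
        for k in idx[1:]:
            same_dir = direction[k] == direction[cur[-1]]
            gap = starts[k] - ends[cur[-1]]
            if same_dir and gap <= merge_gap:
                cur.append(k)
            else:
                rows.append(_emit_region(c, cur, starts, ends, direction,
                                         xt[o:o + n], xc[o:o + n],
                                         s_t, s_c, q[o:o + n]))
                cur = [k]
        rows.append(_emit_region(c, cur, starts, ends, direction,
                                 xt[o:o + n], xc[o:o + n], s_t, s_c, q[o:o + n]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                       "log2fc", "q_min", "n_windows"])


def _emit_region(chrom, members, starts, ends, direction, xt, xc, s_t, s_c, q):
    m = np.asarray(members)
    tt, cc = xt[m].sum(), xc[m].sum()
    region_lfc = float(np.log2(((tt + 0.5) / s_t) / ((cc + 0.5) / s_c)))
    return (chrom, int(starts[m[0]]), int(ends[m[-1]]),
            str(direction[m[0]]), region_lfc, float(np.nanmin(q[m])), len(m))


def annotate_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame,
                  promoter_bp: int = 2_000) -> pd.DataFrame:
    """Feature label per DMR midpoint with precedence promoter (TSS +-
    promoter_bp) > exon > intron > intergenic."""
    tss = cio.gene_tss(genes)
    gchrom = genes["chrom"].to_numpy()
    labels = []
    for _, r in dmrs.iterrows():
        mid = (r["start"] + r["end"]) // 2
        sel = gchrom == r["chrom"]
        label = "intergenic"
        if sel.any():
            if np.any(np.abs(tss[sel] - mid) <= promoter_bp):
                label = "promoter"
            else:
                g = genes[sel]
                inside = g[(g["start"] <= mid) & (mid < g["end"])]
                if len(inside):
                    label = "intron"
                    for _, row in inside.iterrows():
                        bstarts = cio._int_list(row["blockStarts"])
                        bsizes = cio._int_list(row["blockSizes"])
                        for bs, sz in zip(bstarts, bsizes):
                            if row["start"] + bs <= mid < row["start"] + bs + sz:
                                label = "exon"
                                break
                        if label == "exon":
                            break
        labels.append(label)
    out = dmrs.copy()
    out["feature"] = labels
    return out


def feature_composition(annotated: pd.DataFrame) -> dict[str, float]:
    n = len(annotated)
    return {k: (float((annotated["feature"] == k).sum()) / n if n else 0.0)
            for k in ("promoter", "exon", "intron", "intergenic")}


def dmr_peak_overlap(dmrs: pd.DataFrame, peaks: pd.DataFrame) -> dict:
    """Fraction of DMRs sharing >= 1 bp with any peak, plus Venn counts."""
    if len(dmrs) == 0:
        return {"dmrs_total": 0, "dmrs_overlapping": 0, "fraction": 0.0,
                "peaks_total": int(len(peaks)), "peaks_overlapping": 0}
    d_hit = overlap_flags_df(dmrs, peaks) if len(peaks) else np.zeros(len(dmrs), bool)
    p_hit = overlap_flags_df(peaks, dmrs) if len(peaks) else np.zeros(0, bool)
    return {"dmrs_total": int(len(dmrs)),
            "dmrs_overlapping": int(d_hit.sum()),
            "fraction": float(d_hit.sum()) / len(dmrs),
            "peaks_total": int(len(peaks)),
            "peaks_overlapping": int(p_hit.sum())}


def write_dmrs(dmrs: pd.DataFrame, path) -> None:
    dmrs.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def tracks_to_bedgraphs(track: MethylationTrack, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    wf = track.window_frame()
    for cond, reps in track.counts.items():
        for rep, counts in enumerate(reps):
            df = wf.assign(value=counts)
            cio.write_bedgraph(df, outdir / f"medip_{cond}_rep{rep + 1}.bedGraph")
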