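"""A/B compartment calling from 500-kb balanced matrices.

The compartment signal is the first principal component of the per-chromosome
Pearson correlation matrix of the observed/expected map (the Lieberman-Aiden
convention). Positive PC1 is the A compartment, negative is B; the sign of
each chromosome's eigenvector is oriented so that the gene-dense half of its
bins has positive mean PC1 (A = open/gene-dense).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import ContactMatrix, oe_transform
from . import io as cio
from .intervals import points_in_intervals

log = logging.getLogger("chromarch")

COMPARTMENT_RESOLUTION = 500_000
SWITCH_CLASSES = ("A->A", "B->B", "A->B", "B->A")


@dataclass
class CompartmentTrack:
    """Per-500-kb-bin PC1 with A/B labels. ``labels`` holds 'A', 'B' or
    'masked'; masked bins carry NaN PC1."""

    bins: "object"              # BinTable
    pc1: np.ndarray             # global, NaN where masked
    labels: np.ndarray          # object array
    condition: str = ""

    def frame(self) -> pd.DataFrame:
        bf = self.bins.bins_frame().drop(columns="bin_id")
        bf["pc1"] = self.pc1
        bf["label"] = self.labels
        return bf


def _gene_density(bins, genes: pd.DataFrame) -> np.ndarray:
    """TSS count per bin (gene-density anchor for sign orientation)."""
    dens = np.zeros(bins.total_bins)
    tss = cio.gene_tss(genes)
    for c in bins.chroms:
        sel = genes["chrom"].to_numpy() == c
        if not sel.any():
            continue
        idx = bins.bin_of(c, tss[sel])
        np.add.at(dens, bins.offsets[c] + idx, 1.0)
    return dens


def compartment_pc1(matrix: ContactMatrix, genes: pd.DataFrame,
                    condition: str = "", exclude_diags: int = 2) -> CompartmentTrack:
    """PC1 of the O/E correlation matrix per chromosome, sign-oriented by
    gene density, with A/B labels by sign.

    The first ``exclude_diags`` diagonals are excluded from the correlation
    (pairwise-complete), since the near-diagonal band carries domain rather
    than compartment structure. Requires a balanced 500-kb matrix with >= 10
    unmasked bins per chromosome; degenerate chromosomes are masked with a
    warning.
    """
    if matrix.bins.resolution != COMPARTMENT_RESOLUTION:
        raise ValueError(
            f"compartment analysis requires 500 kb matrices, got "
            f"{matrix.bins.resolution} bp")
    if matrix.balanced is None:
        raise ValueError("balanced layer required; run ice_balance first")
    if matrix.oe is None:
        oe_transform(matrix)

    density = _gene_density(matrix.bins, genes)
    pc1 = np.full(matrix.bins.total_bins, np.nan)
    labels = np.full(matrix.bins.total_bins, "masked", dtype=object)

    for c in matrix.bins.chroms:
        off = matrix.bins.offsets[c]
        unm = ~matrix.mask[c]
        if unm.sum() < 10:
            log.warning("%s: fewer than 10 unmasked bins, chromosome masked", c)
            continue
        Z = matrix.oe[c][np.ix_(unm, unm)]
        sd = Z.std(axis=1)
        if np.any(sd == 0):
            keep = sd > 0
            if keep.sum() < 10:
                log.warning("%s: degenerate correlation matrix, chromosome masked", c)
                continue
            sub = np.flatnonzero(unm)[keep]
            unm = np.zeros_like(unm)
            unm[sub] = True
            Z = matrix.oe[c][np.ix_(unm, unm)]
        k = len(Z)
        ii, jj = np.indices((k, k))
        Zm = np.ma.array(Z, mask=np.abs(ii - jj) <= exclude_diags)
        corr = np.asarray(np.ma.corrcoef(Zm, allow_masked=True).filled(0.0))
        np.fill_diagonal(corr, 1.0)
        if not np.all(np.isfinite(corr)):
            log.warning("%s: non-finite correlations, chromosome masked", c)
            continue
        w, v = np.linalg.eigh(corr)
        vec = v[:, -1]

        # orient: gene-dense half of unmasked bins gets positive mean PC1
        dens = density[off:off + matrix.bins.n_bins[c]][unm]
        order = np.argsort(-dens, kind="stable")
        top = order[: max(1, len(order) // 2)]
        if vec[top].mean() < 0:
            vec = -vec
        full = np.full(matrix.bins.n_bins[c], np.nan)
        full[unm] = vec
        pc1[off:off + matrix.bins.n_bins[c]] = full
        lab = np.where(full > 0, "A", np.where(full < 0, "B", "masked"))
        lab[~np.isfinite(full)] = "masked"
        labels[off:off + matrix.bins.n_bins[c]] = lab
    return CompartmentTrack(matrix.bins, pc1, labels, condition)


@dataclass
class SwitchTable:
    """Per-bin compartment switching class between two conditions."""

    bins: "object"
    classes: np.ndarray          # 'A->A', 'B->B', 'A->B', 'B->A' or 'masked'
    fractions: dict[str, float]  # over unmasked bins, sums to 1

    def frame(self) -> pd.DataFrame:
        bf = self.bins.bins_frame().drop(columns="bin_id")
        bf["class"] = self.classes
        return bf


def switch_classify(track_control: CompartmentTrack,
                    track_treated: CompartmentTrack) -> SwitchTable:
    """Classify each bin A->A / B->B / A->B / B->A; fractions over bins
    unmasked in both conditions."""
    if track_control.bins != track_treated.bins:
        raise ValueError("switch_classify requires matching bin tables")
    a = track_control.labels
    b = track_treated.labels
    classes = np.full(len(a), "masked", dtype=object)
    ok = (a != "masked") & (b != "masked")
    classes[ok] = np.char.add(np.char.add(a[ok].astype(str), "->"),
                              b[ok].astype(str))
    n = int(ok.sum())
    fractions = {k: (float((classes == k).sum()) / n if n else 0.0)
                 for k in SWITCH_CLASSES}
    return SwitchTable(track_control.bins, classes, fractions)


def pc1_correlation(track_a: CompartmentTrack,
                    track_b: CompartmentTrack) -> tuple[float, pd.DataFrame]:
    """Pearson r of PC1 over jointly unmasked bins, plus the paired scatter
    table."""
    if track_a.bins != track_b.bins:
        raise ValueError("pc1_correlation requires matching bin tables")
    ok = np.isfinite(track_a.pc1) & np.isfinite(track_b.pc1)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly unmasked bins")
    x, y = track_a.pc1[ok], track_b.pc1[ok]
    r = float(np.corrcoef(x, y)[0, 1])
    bf = track_a.bins.bins_frame().drop(columns="bin_id")[ok]
    scatter = bf.assign(pc1_a=x, pc1_b=y)
    return r, scatter


def peaks_by_compartment(peaks: pd.DataFrame,
                         switch: SwitchTable) -> tuple[dict, dict]:
    """Composition of peaks by switching class of the bin holding the summit,
    and per-class fraction of bins containing >= 1 peak summit."""
    bins = switch.bins
    n_assigned = np.zeros(bins.total_bins, dtype=np.int64)
    peak_class = []
    summits = cio.peak_summits(peaks) if len(peaks) else np.array([], dtype=np.int64)
    unassigned = 0
    for k in range(len(peaks)):
        c = peaks["chrom"].iloc[k]
        if c not in bins.chromsizes or not (0 <= summits[k] < bins.chromsizes[c]):
            unassigned += 1
            continue
        gid = bins.offsets[c] + int(bins.bin_of(c, summits[k]))
        n_assigned[gid] += 1
        peak_class.append(switch.classes[gid])
    if unassigned:
        log.info("%d peaks outside any bin, left unassigned", unassigned)
    peak_class = np.asarray(peak_class, dtype=object)
    tot = len(peak_class)
    composition = {k: (float((peak_class == k).sum()) / tot if tot else 0.0)
                   for k in SWITCH_CLASSES}
    bound_fraction = {}
    for k in SWITCH_CLASSES:
        sel = switch.classes == k
        bound_fraction[k] = (float((n_assigned[sel] > 0).sum()) / sel.sum()
                             if sel.sum() else 0.0)
    return composition, bound_fraction
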