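"""Differential chromatin-interaction calling at 20 kb between two
conditions with replicates.

Replicates are summed per condition and each bin pair is tested with a
two-sided exact binomial test of the treated count against the pooled total,
under the library-size null proportion s_t / (s_t + s_c). Benjamini-Hochberg
correction runs over all tested pairs; a pair is significant when q < fdr
and |log2FC| > lfc (defaults 0.05 and 1). With two replicates per condition
a pooled exact test is the defensible default; replicate concordance is
reported as a diagnostic instead of entering the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .contact import ContactMatrix
from .intervals import overlaps_any
from .stats import binom_test_two_sided, bh_adjust

log = logging.getLogger("chromarch")


@dataclass
class DiffInteractionTable:
    """Tested bin pairs (i <= j) with per-condition counts, log2FC, p, q and
    the significance flag."""

    bins: "object"
    records: pd.DataFrame   # chrom, start_i, end_i, start_j, end_j, count_*, log2fc, p, q, significant
    fdr: float
    lfc: float
    min_count: int
    size_factors: tuple[float, float]    # (control, treated)
    replicate_correlation: dict[str, float]

    def frame(self) -> pd.DataFrame:
        return self.records


def _sum_condition(mats: list[ContactMatrix]) -> dict[str, np.ndarray]:
    out = {c: m.copy() for c, m in mats[0].raw.items()}
    for m in mats[1:]:
        for c in out:
            out[c] = out[c] + m.raw[c]
    return out


def _replicate_correlation(mats: list[ContactMatrix]) -> float:
    """Pearson r of upper-triangle counts between the first two replicates."""
    if len(mats) < 2:
        return float("nan")
    xs, ys = [], []
    for c in mats[0].raw:
        iu = np.triu_indices(mats[0].raw[c].shape[0])
        xs.append(mats[0].raw[c][iu])
        ys.append(mats[1].raw[c][iu])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])


def call_differential(control: list[ContactMatrix], treated: list[ContactMatrix],
                      min_count: int = 10, fdr: float = 0.05,
                      lfc: float = 1.0) -> DiffInteractionTable:
    """Test every cis bin pair with summed raw count >= min_count.

    log2FC is computed from size-factor-scaled counts with pseudocount 0.5:
    log2(((x_t + 0.5)/s_t) / ((x_c + 0.5)/s_c)), antisymmetric under
    condition swap."""
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 replicates per condition")
    bins = control[0].bins
    for m in control + treated:
        if m.bins != bins:
            raise ValueError("all matrices must share one bin table")
    Xc = _sum_condition(control)
    Xt = _sum_condition(treated)
    s_c = sum(np.triu(m).sum() for m in Xc.values())
    s_t = sum(np.triu(m).sum() for m in Xt.values())
    if s_c <= 0 or s_t <= 0:
        raise ValueError("zero library size in one condition")

    frames = []
    for c in bins.chroms:
        n = Xc[c].shape[0]
        iu, ju = np.triu_indices(n)
        xc = Xc[c][iu, ju]
        xt = Xt[c][iu, ju]
        keep = (xc + xt) >= min_count
        if not keep.any():
            continue
        res = bins.resolution
        frames.append(pd.DataFrame({
            "chrom": c,
            "start_i": iu[keep] * res, "end_i": (iu[keep] + 1) * res,
            "start_j": ju[keep] * res, "end_j": (ju[keep] + 1) * res,
            "count_control": xc[keep].astype(np.int64),
            "count_treated": xt[keep].astype(np.int64)}))
    if not frames:
        records = pd.DataFrame(columns=[
            "chrom", "start_i", "end_i", "start_j", "end_j", "count_control",
            "count_treated", "log2fc", "p", "q", "significant"])
        return DiffInteractionTable(bins, records, fdr, lfc, min_count,
                                    (s_c, s_t), {})
    records = pd.concat(frames, ignore_index=True)
    xt = records["count_treated"].to_numpy()
    xc = records["count_control"].to_numpy()
    p0 = s_t / (s_t + s_c)
    # difference of logs: bitwise-exact negation under condition swap
    records["log2fc"] = (np.log2((xt + 0.5) / s_t)
                         - np.log2((xc + 0.5) / s_c))
    records["p"] = binom_test_two_sided(xt, xt + xc, p0)
    records["q"] = bh_adjust(records["p"].to_numpy())
    records["significant"] = (records["q"] < fdr) & \
        (records["log2fc"].abs() > lfc)
    repcor = {"control": _replicate_correlation(control),
              "treated": _replicate_correlation(treated)}
    return DiffInteractionTable(bins, records, fdr, lfc, min_count,
                                (float(s_c), float(s_t)), repcor)


def differential_bins(table: DiffInteractionTable) -> pd.DataFrame:
    """Bins participating in >= 1 significant pair (union of endpoints)."""
    sig = table.records[table.records["significant"]]
    rows = set()
    for _, r in sig.iterrows():
        rows.add((r["chrom"], int(r["start_i"]), int(r["end_i"])))
        rows.add((r["chrom"], int(r["start_j"]), int(r["end_j"])))
    df = pd.DataFrame(sorted(rows), columns=["chrom", "start", "end"])
    return df


def overlap_with_peaks(bins_df: pd.DataFrame, peaks: pd.DataFrame) -> dict:
    """Venn counts: peaks overlapping >=1 differential bin (and vice versa)
    by the >= 1 bp rule."""
    if bins_df.empty or peaks.empty:
        return {"peaks_total": int(len(peaks)), "bins_total": int(len(bins_df)),
                "peaks_overlapping": 0, "bins_with_peak": 0}
    pk_hit = np.zeros(len(peaks), dtype=bool)
    bin_hit = np.zeros(len(bins_df), dtype=bool)
    for c in bins_df["chrom"].unique():
        b = bins_df[bins_df["chrom"] == c]
        p = peaks[peaks["chrom"] == c]
        if p.empty:
            continue
        hp = overlaps_any(p["start"].to_numpy(), p["end"].to_numpy(),
                          b["start"].to_numpy(), b["end"].to_numpy())
        hb = overlaps_any(b["start"].to_numpy(), b["end"].to_numpy(),
                          p["start"].to_numpy(), p["end"].to_numpy())
        pk_hit[peaks.index.get_indexer(p.index)] = hp
        bin_hit[bins_df.index.get_indexer(b.index)] = hb
    return {"peaks_total": int(len(peaks)), "bins_total": int(len(bins_df)),
            "peaks_overlapping": int(pk_hit.sum()),
            "bins_with_peak": int(bin_hit.sum())}


def counts_by_binding(table: DiffInteractionTable,
                      peaks: pd.DataFrame) -> dict:
    """Per tested bin: number of significant pairs it participates in, split
    by whether >= 1 peak overlaps the bin; two-sided Mann-Whitney between
    the bound and unbound groups."""
    rec = table.records
    res = table.bins.resolution
    # every tested bin (endpoint of any tested pair)
    counts: dict[tuple, int] = {}
    for _, r in rec.iterrows():
        for s in (int(r["start_i"]), int(r["start_j"])):
            key = (r["chrom"], s)
            counts[key] = counts.get(key, 0) + (1 if r["significant"] else 0)
    if not counts:
        return {"bound": np.array([]), "unbound": np.array([]), "p": np.nan}
    bins_df = pd.DataFrame([(c, s, s + res) for c, s in counts],
                           columns=["chrom", "start", "end"])
    vals = np.array(list(counts.values()), dtype=float)
    bound = np.zeros(len(bins_df), dtype=bool)
    for c in bins_df["chrom"].unique():
        sel = bins_df["chrom"] == c
        p = peaks[peaks["chrom"] == c] if len(peaks) else peaks
        if len(p) == 0:
            continue
        bound[sel.to_numpy()] = overlaps_any(
            bins_df.loc[sel, "start"].to_numpy(),
            bins_df.loc[sel, "end"].to_numpy(),
            p["start"].to_numpy(), p["end"].to_numpy())
    g_bound = vals[bound]
    g_unbound = vals[~bound]
    if len(g_bound) == 0 or len(g_unbound) == 0:
        log.info("counts_by_binding: one group empty, comparison skipped")
        pval = np.nan
    elif np.all(vals == vals[0]):
        pval = 1.0
    else:
        pval = float(mannwhitneyu(g_bound, g_unbound,
                                  alternative="two-sided").pvalue)
    return {"bound": g_bound, "unbound": g_unbound, "p": pval}


def write_table_bedpe(table: DiffInteractionTable, path) -> None:
    rec = table.records.copy()
    rec.insert(5, "chrom_j", rec["chrom"])
    rec = rec.rename(columns={"chrom": "chrom_i"})
    rec.to_csv(path, sep="\t", index=False, float_format="%.6g")
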