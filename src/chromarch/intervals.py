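"""Genomic interval algebra on plain numpy arrays.

All intervals are 0-based half-open. Functions operate per chromosome on
sorted or unsorted coordinate arrays; callers group by chromosome. The
implementations are O((n+m) log m) sorted-scan variants; the test suite
checks them against quadratic brute-force oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def overlaps_any(starts_a: np.ndarray, ends_a: np.ndarray,
                 starts_b: np.ndarray, ends_b: np.ndarray) -> np.ndarray:
    """For each interval in A, whether it shares >=1 bp with any interval in B."""
    starts_a = np.asarray(starts_a)
    ends_a = np.asarray(ends_a)
    if len(starts_b) == 0:
        return np.zeros(len(starts_a), dtype=bool)
    order = np.argsort(starts_b, kind="stable")
    bs = np.asarray(starts_b)[order]
    be = np.asarray(ends_b)[order]
    # prefix max of ends over B sorted by start
    be_max = np.maximum.accumulate(be)
    # candidates: B intervals with start < a.end
    idx = np.searchsorted(bs, ends_a, side="left")
    hit = np.zeros(len(starts_a), dtype=bool)
    nz = idx > 0
    hit[nz] = be_max[idx[nz] - 1] > starts_a[nz]
    return hit


def count_overlaps(starts_a, ends_a, starts_b, ends_b) -> np.ndarray:
    """Number of B intervals sharing >=1 bp with each A interval."""
    starts_a = np.asarray(starts_a)
    ends_a = np.asarray(ends_a)
    bs = np.sort(np.asarray(starts_b))
    be = np.sort(np.asarray(ends_b))
    # count(b.start < a.end) - count(b.end <= a.start)
    lo = np.searchsorted(bs, ends_a, side="left")
    hi = np.searchsorted(be, starts_a, side="right")
    return lo - hi


def points_in_intervals(points: np.ndarray, starts: np.ndarray,
                        ends: np.ndarray) -> np.ndarray:
    """Index of the (sorted, non-overlapping) interval containing each point, -1 if none."""
    points = np.asarray(points)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = (idx >= 0) & (points < ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1)


def nearest_point(query: np.ndarray, targets: np.ndarray):
    """Nearest target for each query point: (index into sorted-unique order of
    the original targets array, signed distance query-target).

    Ties broken toward the smaller-coordinate target (deterministic).
    """
    query = np.asarray(query)
    targets = np.asarray(targets)
    order = np.argsort(targets, kind="stable")
    t = targets[order]
    pos = np.searchsorted(t, query)
    left = np.clip(pos - 1, 0, len(t) - 1)
    right = np.clip(pos, 0, len(t) - 1)
    dl = np.abs(query - t[left])
    dr = np.abs(query - t[right])
    pick_left = dl <= dr
    idx_sorted = np.where(pick_left, left, right)
    return order[idx_sorted], query - t[idx_sorted]


def reciprocal_overlap_pairs(a: pd.DataFrame, b: pd.DataFrame,
                             min_frac: float = 0.5) -> list[tuple[int, int]]:
    """Pairs (ia, ib) of row positions whose intervals overlap reciprocally.

    Both frames need chrom/start/end columns. Reciprocal: the overlap covers
    >= min_frac of each interval's length. Interval sets are small (TADs), so
    a per-chromosome sweep is used.
    """
    pairs = []
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        for ia, ra in ga.iterrows():
            ov = np.minimum(gb["end"].to_numpy(), ra["end"]) - \
                np.maximum(gb["start"].to_numpy(), ra["start"])
            la = ra["end"] - ra["start"]
            lb = (gb["end"] - gb["start"]).to_numpy()
            ok = (ov >= min_frac * la) & (ov >= min_frac * lb) & (ov > 0)
            for ib in gb.index[ok]:
                pairs.append((ia, ib))
    return pairs


def overlap_flags_df(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """>=1 bp overlap flag for each row of A against interval set B (chrom-aware)."""
    flags = np.zeros(len(a), dtype=bool)
    a_idx = np.arange(len(a))
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b[b["chrom"] == chrom]
        sel = a_idx[a["chrom"].to_numpy() == chrom]
        if gb.empty:
            continue
        flags[sel] = overlaps_any(ga["start"].to_numpy(), ga["end"].to_numpy(),
                                  gb["start"].to_numpy(), gb["end"].to_numpy())
    return flags
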