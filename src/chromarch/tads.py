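"""TAD calling by directionality index + HMM, boundary assembly with the
<400 kb rule, boundary-strength scoring, intra-TAD interaction statistics and
TAD-level compartment scores.

Directionality index (DI) per 40-kb bin: with A the sum of balanced contacts
to bins within a window W upstream, B the sum within W downstream and
E = (A+B)/2,

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

A three-state Gaussian HMM (upstream-biased / unbiased / downstream-biased)
is fit to the DI values by EM and Viterbi-decoded; a domain opens at the
first bin of a downstream-biased run and closes at the last bin of the next
upstream-biased run. Gaps between consecutive domains shorter than 400 kb
are TAD boundaries; longer gaps are unorganized chromatin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.stats import mannwhitneyu

from .contact import ContactMatrix
from .intervals import overlaps_any, reciprocal_overlap_pairs, overlap_flags_df

log = logging.getLogger("chromarch")

TAD_RESOLUTION = 40_000
BOUNDARY_MAX_BP = 400_000       # gaps below this are boundaries, else unorganized
DEFAULT_DI_WINDOW = 2_000_000   # 50 bins at 40 kb
STATE_UP, STATE_NONE, STATE_DOWN = 0, 1, 2


@dataclass
class DIVector:
    """Per-bin directionality index with the audit fields A, B, E retained."""

    bins: "object"                  # BinTable
    window: int
    di: dict[str, np.ndarray]
    upstream: dict[str, np.ndarray]     # A
    downstream: dict[str, np.ndarray]   # B
    expected: dict[str, np.ndarray]     # E = (A+B)/2
    partial: dict[str, np.ndarray]      # True for edge bins with truncated window

    def frame(self) -> pd.DataFrame:
        rows = []
        for c in self.bins.chroms:
            n = self.bins.n_bins[c]
            starts = np.arange(n) * self.bins.resolution
            rows.append(pd.DataFrame({
                "chrom": c, "start": starts,
                "end": np.minimum(starts + self.bins.resolution,
                                  self.bins.chromsizes[c]),
                "di": self.di[c], "A": self.upstream[c], "B": self.downstream[c],
                "E": self.expected[c], "partial": self.partial[c]}))
        return pd.concat(rows, ignore_index=True)


def directionality_index(matrix: ContactMatrix,
                         window: int = DEFAULT_DI_WINDOW) -> DIVector:
    """DI per bin of the balanced layer. ``window`` must be a positive
    multiple of the resolution; edge bins with a truncated window are
    computed over the available span and flagged partial."""
    res = matrix.bins.resolution
    if window < res or window % res:
        raise ValueError(f"window must be a positive multiple of the "
                         f"resolution ({res} bp)")
    if matrix.balanced is None:
        raise ValueError("balanced layer required; run ice_balance first")
    wb = window // res
    di, A_, B_, E_, P_ = {}, {}, {}, {}, {}
    for c in matrix.bins.chroms:
        N = matrix.balanced[c]
        n = N.shape[0]
        cs = np.concatenate([np.zeros((n, 1)), np.cumsum(N, axis=1)], axis=1)
        i = np.arange(n)
        lo = np.maximum(i - wb, 0)
        hi = np.minimum(i + wb, n - 1)
        A = cs[i, i] - cs[i, lo]                  # j in [i-wb, i-1]
        B = cs[i, hi + 1] - cs[i, i + 1]          # j in [i+1, i+wb]
        E = (A + B) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.sign(B - A) * ((A - E) ** 2 + (B - E) ** 2) / E
        val[E == 0] = 0.0
        di[c], A_[c], B_[c], E_[c] = val, A, B, E
        P_[c] = (i < wb) | (i > n - 1 - wb)
    return DIVector(matrix.bins, window, di, A_, B_, E_, P_)


def fit_hmm_and_decode(div: DIVector, seed: int = 13) -> dict[str, np.ndarray]:
    """Fit one 3-state Gaussian HMM on the pooled genome and Viterbi-decode
    each chromosome. States are relabeled by ordered means so 0 =
    upstream-biased, 1 = unbiased, 2 = downstream-biased."""
    chroms = div.bins.chroms
    series = [np.nan_to_num(div.di[c], nan=0.0) for c in chroms]
    pooled = np.concatenate(series)
    for c in chroms:
        if np.isfinite(div.di[c]).sum() < 50:
            raise ValueError(f"{c}: need >= 50 finite DI values")
    if pooled.std() < 1e-12:
        return {c: np.full(len(s), STATE_NONE, dtype=np.int8)
                for c, s in zip(chroms, series)}

    X = pooled[:, None]
    lengths = [len(s) for s in series]

    def build(perturb: float) -> GaussianHMM:
        hmm = GaussianHMM(n_components=3, covariance_type="diag",
                          init_params="", params="stmc",
                          n_iter=200, tol=1e-4, random_state=seed,
                          min_covar=1e-6)
        q = np.quantile(pooled, [0.1, 0.5, 0.9])
        if perturb:
            q = q + perturb * pooled.std() * np.array([-1.0, 0.5, 1.0])
        hmm.startprob_ = np.full(3, 1 / 3)
        hmm.transmat_ = np.full((3, 3), 0.05) + np.eye(3) * 0.85
        hmm.means_ = q[:, None]
        hmm.covars_ = np.full((3, 1), max(pooled.var(), 1e-6))
        return hmm

    hmm = build(0.0)
    try:
        hmm.fit(X, lengths)
        if np.any(hmm.covars_ <= 0) or not np.all(np.isfinite(hmm.means_)):
            raise ValueError("degenerate variance")
    except Exception as err:  # retry once with perturbed initialization
        log.warning("HMM fit failed (%s); retrying with perturbed init", err)
        hmm = build(0.3)
        hmm.fit(X, lengths)
        if np.any(hmm.covars_ <= 0) or not np.all(np.isfinite(hmm.means_)):
            raise RuntimeError("HMM fit degenerate after retry")

    order = np.argsort(hmm.means_.ravel())
    relabel = np.empty(3, dtype=np.int8)
    relabel[order] = [STATE_UP, STATE_NONE, STATE_DOWN]
    out = {}
    for c, s in zip(chroms, series):
        path = hmm.predict(s[:, None])
        out[c] = relabel[path]
    return out


@dataclass
class TadSet:
    """Called domains plus inter-domain regions classified by the 400-kb rule."""

    domains: pd.DataFrame      # chrom, start, end
    boundaries: pd.DataFrame   # chrom, start, end, kind, strength
    condition: str = ""

    def boundary_regions(self) -> pd.DataFrame:
        return self.boundaries[self.boundaries["kind"] == "boundary"].reset_index(drop=True)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, first_bin, last_bin) runs of a state path."""
    out = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            out.append((int(states[start]), start, k - 1))
            start = k
    return out


def assemble_domains(state_paths: dict[str, np.ndarray], bins,
                     condition: str = "") -> TadSet:
    """Domains from decoded state paths; inter-domain gaps < 400 kb become
    boundaries, >= 400 kb unorganized regions, and zero-length gaps a 1-bp
    boundary at the shared edge."""
    res = bins.resolution
    dom_rows, bnd_rows = [], []
    for c in bins.chroms:
        states = state_paths.get(c)
        if states is None or len(states) == 0:
            continue
        runs = _runs(np.asarray(states))
        doms = []
        k = 0
        while k < len(runs):
            st, s, _ = runs[k]
            if st == STATE_DOWN:
                close = None
                for j in range(k + 1, len(runs)):
                    if runs[j][0] == STATE_UP:
                        close = j
                        break
                if close is None:
                    break
                doms.append((s, runs[close][2]))
                k = close + 1
            else:
                k += 1
        chrom_end = bins.chromsizes[c]
        for s, e in doms:
            dom_rows.append((c, s * res, min((e + 1) * res, chrom_end)))
        for (s1, e1), (s2, e2) in zip(doms[:-1], doms[1:]):
            gap_start = (e1 + 1) * res
            gap_end = s2 * res
            gap = gap_end - gap_start
            if gap == 0:
                bnd_rows.append((c, gap_start, gap_start + 1, "boundary"))
            elif gap < BOUNDARY_MAX_BP:
                bnd_rows.append((c, gap_start, gap_end, "boundary"))
            else:
                bnd_rows.append((c, gap_start, gap_end, "unorganized"))
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])
    boundaries = pd.DataFrame(bnd_rows, columns=["chrom", "start", "end", "kind"])
    boundaries["strength"] = np.nan
    return TadSet(domains, boundaries, condition)


def tadset_from_domains(domains: pd.DataFrame, condition: str = "") -> TadSet:
    """TadSet from an explicit domain list (e.g. planted truth); gap rules as
    in assemble_domains."""
    bnd_rows = []
    d = domains.sort_values(["chrom", "start"])
    for c, g in d.groupby("chrom", sort=False):
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        for gap_start, gap_end in zip(e[:-1], s[1:]):
            gap = gap_end - gap_start
            if gap == 0:
                bnd_rows.append((c, gap_start, gap_start + 1, "boundary"))
            elif gap < BOUNDARY_MAX_BP:
                bnd_rows.append((c, gap_start, gap_end, "boundary"))
            else:
                bnd_rows.append((c, gap_start, gap_end, "unorganized"))
    boundaries = pd.DataFrame(bnd_rows, columns=["chrom", "start", "end", "kind"])
    boundaries["strength"] = np.nan
    return TadSet(d.reset_index(drop=True)[["chrom", "start", "end"]],
                  boundaries, condition)


def boundary_strength(matrix: ContactMatrix, tads: TadSet,
                      flank_bins: int = 10) -> TadSet:
    """Insulation score per boundary from the O/E layer.

    For a boundary with first overlapped bin bs and last overlapped bin be,
    with flank w: left block L = [bs-w, bs), right block R = [be+1, be+w+1),
    S = log2(mean(Z over L x L and R x R) / mean(Z over L x R)). Higher S =
    stronger insulation; boundaries within w bins of a chromosome edge are
    left unscored."""
    if flank_bins < 2:
        raise ValueError("flank must be >= 2 bins")
    if matrix.oe is None:
        raise ValueError("O/E layer required; run oe_transform first")
    res = matrix.bins.resolution
    w = flank_bins
    strengths = np.full(len(tads.boundaries), np.nan)
    for k, row in tads.boundaries.reset_index(drop=True).iterrows():
        if row["kind"] != "boundary":
            continue
        c = row["chrom"]
        Z = matrix.oe[c]
        n = Z.shape[0]
        bs = int(row["start"]) // res
        be = (int(row["end"]) - 1) // res
        if bs - w < 0 or be + 1 + w > n:
            log.info("boundary %s:%d-%d within %d bins of chromosome edge, unscored",
                     c, row["start"], row["end"], w)
            continue
        L = slice(bs - w, bs)
        R = slice(be + 1, be + 1 + w)
        intra = np.concatenate([Z[L, L].ravel(), Z[R, R].ravel()])
        cross = Z[L, R].ravel()
        mi, mc = intra.mean(), cross.mean()
        if mi > 0 and mc > 0:
            strengths[k] = np.log2(mi / mc)
    out = TadSet(tads.domains.copy(), tads.boundaries.copy(), tads.condition)
    out.boundaries["strength"] = strengths
    return out


def intra_tad_interaction(matrix: ContactMatrix, tads: TadSet) -> pd.DataFrame:
    """Mean off-diagonal O/E within each domain (>= 3 bins; smaller domains
    skipped with a log entry)."""
    if matrix.oe is None:
        raise ValueError("O/E layer required; run oe_transform first")
    res = matrix.bins.resolution
    rows = []
    for _, row in tads.domains.iterrows():
        c = row["chrom"]
        b0 = int(row["start"]) // res
        b1 = -(-int(row["end"]) // res)      # ceil: bins overlapped
        unm = ~matrix.mask[c][b0:b1]
        idx = np.flatnonzero(unm) + b0
        if len(idx) < 3:
            log.info("domain %s:%d-%d spans < 3 usable bins, skipped",
                     c, row["start"], row["end"])
            continue
        Z = matrix.oe[c][np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        rows.append((c, int(row["start"]), int(row["end"]),
                     float(Z[iu].mean()), len(idx)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_oe", "n_bins"])


def compare_conditions(means_a, means_b) -> tuple[float, float]:
    """Median difference (b - a) of per-TAD means and two-sided Mann-Whitney p."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    shift = float(np.median(b) - np.median(a))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty per-TAD mean list")
    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return shift, p


def tad_compartment_scores(tads: TadSet, track) -> pd.DataFrame:
    """Mean PC1 over the 500-kb bins whose midpoints fall inside each domain;
    label A if positive, B if negative, masked when zero or no located bins."""
    bins = track.bins
    rows = []
    bf = bins.bins_frame()
    mids = ((bf["start"] + bf["end"]) // 2).to_numpy()
    for _, row in tads.domains.iterrows():
        sel = ((bf["chrom"] == row["chrom"]).to_numpy()
               & (mids >= row["start"]) & (mids < row["end"]))
        vals = track.pc1[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append((row["chrom"], row["start"], row["end"], np.nan, "masked"))
            continue
        score = float(vals.mean())
        label = "A" if score > 0 else ("B" if score < 0 else "masked")
        rows.append((row["chrom"], row["start"], row["end"], score, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "label"])


def tad_switch(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> tuple[float, int]:
    """Fraction of label switches over TAD pairs matched by >= 50% reciprocal
    overlap (both TADs labeled). Returns (switched_fraction, n_matched)."""
    pairs = reciprocal_overlap_pairs(scores_a.reset_index(drop=True),
                                     scores_b.reset_index(drop=True), 0.5)
    n = 0
    sw = 0
    for ia, ib in pairs:
        la = scores_a.iloc[ia]["label"]
        lb = scores_b.iloc[ib]["label"]
        if la == "masked" or lb == "masked":
            continue
        n += 1
        sw += la != lb
    return (sw / n if n else 0.0), n


def boundary_strength_strata(tads_a: TadSet, tads_b: TadSet,
                             peaks: pd.DataFrame) -> dict:
    """Boundary score distributions grouped two ways: boundaries overlapping
    between conditions vs condition-specific, and peak-bound vs unbound.

    Matching across conditions is >= 1 bp overlap of boundary regions; a
    boundary is bound when >= 1 peak overlaps it. Mann-Whitney p-values are
    reported where both groups are non-empty."""
    out = {}
    for tag, own, other in (("a", tads_a, tads_b), ("b", tads_b, tads_a)):
        bnd = own.boundary_regions()
        obnd = other.boundary_regions()
        shared = overlap_flags_df(bnd, obnd)
        bound = overlap_flags_df(bnd, peaks) if len(peaks) else np.zeros(len(bnd), bool)
        s = bnd["strength"].to_numpy(dtype=float)
        ok = np.isfinite(s)
        groups = {
            "overlapping": s[ok & shared], "specific": s[ok & ~shared],
            "bound": s[ok & bound], "unbound": s[ok & ~bound]}
        res = {k: v for k, v in groups.items()}
        for pair in (("overlapping", "specific"), ("bound", "unbound")):
            g1, g2 = groups[pair[0]], groups[pair[1]]
            key = f"p_{pair[0]}_vs_{pair[1]}"
            if len(g1) and len(g2):
                res[key] = float(mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
            else:
                log.info("condition %s: empty group in %s comparison, skipped",
                         tag, pair)
                res[key] = np.nan
        res["n_overlapping"] = int((shared & ok).sum())
        res["n_specific"] = int((~shared & ok).sum())
        out[tag] = res
    return out


def boundary_recall(called: TadSet, truth_boundaries: pd.DataFrame,
                    resolution: int = TAD_RESOLUTION,
                    tol_bins: int = 1) -> float:
    """Fraction of planted boundary positions matched by a called boundary
    midpoint within +- tol_bins bins."""
    if truth_boundaries.empty:
        raise ValueError("no planted boundaries")
    bnd = called.boundary_regions()
    hit = 0
    for _, row in truth_boundaries.iterrows():
        g = bnd[bnd["chrom"] == row["chrom"]]
        if g.empty:
            continue
        mids = ((g["start"] + g["end"]) // 2).to_numpy()
        if np.any(np.abs(mids - row["pos"]) <= tol_bins * resolution):
            hit += 1
    return hit / len(truth_boundaries)


def write_tadset(tads: TadSet, domains_path, boundaries_path) -> None:
    tads.domains.assign(name="domain").to_csv(
        domains_path, sep="\t", header=False, index=False)
    tads.boundaries.to_csv(boundaries_path, sep="\t", header=False,
                           index=False, float_format="%.6g")


def read_tadset(domains_path, boundaries_path, condition: str = "") -> TadSet:
    doms = pd.read_csv(domains_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name"])[["chrom", "start", "end"]]
    bnds = pd.read_csv(boundaries_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "kind", "strength"])
    return TadSet(doms, bnds, condition)
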