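"""Contact-matrix data model, HiC-Pro-dialect I/O, ICE balancing and
observed/expected transforms.

The model is cis-only: one dense symmetric matrix per chromosome. Raw counts,
the ICE-balanced layer and the observed/expected (O/E) layer live side by
side on the same :class:`ContactMatrix`. Masked (filtered) bins have all-zero
rows and columns in every layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("chromarch")


class BinTable:
    """Fixed-resolution tiling of a chromosome set into bins.

    Bins tile each chromosome without gaps or overlaps; every bin except
    possibly the last per chromosome has length ``resolution``. Global bin
    IDs are 0-based and ordered by chromosome insertion order.
    """

    def __init__(self, chromsizes: dict[str, int], resolution: int):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.chromsizes = dict(chromsizes)
        self.chroms = list(self.chromsizes)
        self.n_bins = {c: -(-l // resolution) for c, l in self.chromsizes.items()}
        self.offsets = {}
        off = 0
        for c in self.chroms:
            self.offsets[c] = off
            off += self.n_bins[c]
        self.total_bins = off

    def __eq__(self, other):
        return (isinstance(other, BinTable)
                and self.resolution == other.resolution
                and self.chromsizes == other.chromsizes)

    def bins_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            n = self.n_bins[c]
            starts = np.arange(n) * self.resolution
            ends = np.minimum(starts + self.resolution, self.chromsizes[c])
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends,
                                      "bin_id": self.offsets[c] + np.arange(n)}))
        return pd.concat(rows, ignore_index=True)

    def bin_of(self, chrom: str, pos) -> np.ndarray:
        """Chromosome-local bin index of base-pair position(s)."""
        pos = np.asarray(pos)
        idx = pos // self.resolution
        return np.clip(idx, 0, self.n_bins[chrom] - 1).astype(np.int64)

    def to_bed(self, path) -> None:
        df = self.bins_frame()
        df["bin_id"] += 1  # HiC-Pro companion bed carries 1-based IDs
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "BinTable":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "bin_id"])
        sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
        lengths = (df["end"] - df["start"]).to_numpy()
        resolution = int(np.max(lengths))
        table = cls(sizes, resolution)
        if table.total_bins != len(df):
            raise ValueError(f"{path}: bins do not tile chromosomes at "
                             f"resolution {resolution}")
        return table


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric cis contact matrices with raw / balanced /
    O/E layers, a per-bin bias vector and a filtered-bin mask."""

    bins: BinTable
    raw: dict[str, np.ndarray]
    balanced: dict[str, np.ndarray] | None = None
    oe: dict[str, np.ndarray] | None = None
    bias: dict[str, np.ndarray] | None = None
    mask: dict[str, np.ndarray] = field(default_factory=dict)  # True = filtered

    def __post_init__(self):
        for c, m in self.raw.items():
            n = self.bins.n_bins[c]
            if m.shape != (n, n):
                raise ValueError(f"{c}: matrix shape {m.shape} != bins {n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{c}: raw matrix not symmetric")
        for c in self.raw:
            self.mask.setdefault(c, np.zeros(self.bins.n_bins[c], dtype=bool))

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins, {c: m.copy() for c, m in self.raw.items()},
            None if self.balanced is None else {c: m.copy() for c, m in self.balanced.items()},
            None if self.oe is None else {c: m.copy() for c, m in self.oe.items()},
            None if self.bias is None else {c: b.copy() for c, b in self.bias.items()},
            {c: m.copy() for c, m in self.mask.items()})


def read_matrix(matrix_path, bins_path) -> ContactMatrix:
    """Read a HiC-Pro-dialect triplet ``.matrix`` + bin ``.bed`` pair.

    Triplet lines are ``bin_i<TAB>bin_j<TAB>count`` with 1-based global bin
    IDs and i <= j (upper triangle). The lower triangle is reconstructed by
    symmetry.
    """
    bins = BinTable.from_bed(bins_path)
    chrom_of = np.empty(bins.total_bins, dtype=object)
    local = np.empty(bins.total_bins, dtype=np.int64)
    for c in bins.chroms:
        o, n = bins.offsets[c], bins.n_bins[c]
        chrom_of[o:o + n] = c
        local[o:o + n] = np.arange(n)

    mats = {c: np.zeros((bins.n_bins[c], bins.n_bins[c])) for c in bins.chroms}
    seen = set()
    with open(matrix_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{matrix_path}:{ln}: expected 3 fields")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            count = float(parts[2])
            if not (0 <= i < bins.total_bins and 0 <= j < bins.total_bins):
                raise ValueError(f"{matrix_path}:{ln}: unknown bin ID")
            if count < 0:
                raise ValueError(f"{matrix_path}:{ln}: negative count")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"{matrix_path}:{ln}: duplicate record for "
                                 f"bin pair {key[0] + 1},{key[1] + 1}")
            seen.add(key)
            if chrom_of[i] != chrom_of[j]:
                raise ValueError(f"{matrix_path}:{ln}: trans contact "
                                 f"({chrom_of[i]} vs {chrom_of[j]}); model is cis-only")
            c = chrom_of[i]
            a, b = local[i], local[j]
            mats[c][a, b] = count
            mats[c][b, a] = count
    return ContactMatrix(bins, mats)


def write_matrix(matrix: ContactMatrix, matrix_path, bins_path,
                 layer: str = "raw") -> None:
    """Write the upper triangle of a layer in the HiC-Pro triplet dialect."""
    matrix.bins.to_bed(bins_path)
    data = getattr(matrix, layer)
    if data is None:
        raise ValueError(f"layer {layer!r} not present")
    frames = []
    for c in matrix.bins.chroms:
        m = data[c]
        off = matrix.bins.offsets[c]
        iu, ju = np.nonzero(np.triu(m))
        frames.append(pd.DataFrame({"i": off + iu + 1, "j": off + ju + 1,
                                    "count": m[iu, ju]}))
    out = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["i", "j", "count"])
    vals = out["count"].to_numpy()
    if len(vals) and np.all(np.mod(vals, 1) == 0):
        out["count"] = vals.astype(np.int64)
        out.to_csv(matrix_path, sep="\t", header=False, index=False)
    else:
        out.to_csv(matrix_path, sep="\t", header=False, index=False,
                   float_format="%.10g")


def ice_balance(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                mask_fraction: float = 0.02) -> tuple[ContactMatrix, dict[str, np.ndarray]]:
    """Iterative correction (ICE) of the raw layer, per chromosome.

    Each iteration divides rows/columns by their marginal sums renormalized
    to mean one, until the coefficient of variation of the unmasked row sums
    drops below ``tol`` or ``max_iter`` is reached. The lowest
    ``mask_fraction`` of bins by raw coverage (plus zero-coverage bins) are
    masked first. The returned bias is normalized to geometric mean 1 over
    unmasked bins so the balanced layer keeps the raw count scale;
    ``N_ij = O_ij / (b_i b_j)``.
    """
    if not (0.0 <= mask_fraction < 1.0):
        raise ValueError("mask_fraction must be in [0, 1)")
    balanced = {}
    bias = {}
    for c in matrix.bins.chroms:
        O = matrix.raw[c].astype(float)
        n = O.shape[0]
        coverage = O.sum(axis=1)
        mask = coverage <= 0
        k = int(np.floor(mask_fraction * n))
        if k > 0:
            order = np.argsort(coverage, kind="stable")
            mask[order[:k]] = True
        if mask.all():
            raise ValueError(f"{c}: all bins masked, cannot balance")
        W = O.copy()
        W[mask, :] = 0.0
        W[:, mask] = 0.0
        b = np.ones(n)
        cv = np.inf
        for _ in range(max_iter):
            s = W.sum(axis=1)
            su = s[~mask]
            mean = su.mean()
            if mean <= 0:
                raise ValueError(f"{c}: zero total coverage after masking")
            cv = su.std() / mean
            if cv < tol:
                break
            # square-root damping: symmetric scaling overshoots without it
            r = np.sqrt(s / mean)
            r[mask] = 1.0
            r[r == 0] = 1.0
            W /= np.outer(r, r)
            b *= r
        else:
            log.warning("%s: ICE did not converge in %d iterations (CV=%.3g)",
                        c, max_iter, cv)
        g = np.exp(np.log(b[~mask]).mean())
        b /= g
        N = matrix.raw[c] / np.outer(b, b)
        N[mask, :] = 0.0
        N[:, mask] = 0.0
        bfull = b.copy()
        bfull[mask] = np.nan
        balanced[c] = N
        bias[c] = bfull
        matrix.mask[c] = mask
    matrix.balanced = balanced
    matrix.bias = bias
    return matrix, bias


@dataclass
class ExpectedProfile:
    """Distance-decay summary: per-chromosome mean balanced contact E(s) at
    each bin distance s, plus a pooled frequency density over log10(bp)."""

    resolution: int
    expected: dict[str, np.ndarray]        # E[s] indexed by bin distance, NaN if empty
    density: pd.DataFrame                  # columns: log10_lo, log10_hi, density

    def slope(self, min_bp: float = 200_000, max_bp: float = 5_000_000) -> float:
        """Least-squares slope of log10 E(s) vs log10 s over a bp range,
        pooled over chromosomes (s > 0 bins with defined E)."""
        xs, ys = [], []
        for c, e in self.expected.items():
            s = np.arange(len(e)) * self.resolution
            ok = (s >= min_bp) & (s <= max_bp) & np.isfinite(e) & (e > 0)
            xs.append(np.log10(s[ok]))
            ys.append(np.log10(e[ok]))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(x) < 2:
            raise ValueError("not enough distance points to fit a slope")
        return float(np.polyfit(x, y, 1)[0])


def expected_profile(matrix: ContactMatrix, density_binwidth: float = 0.1) -> ExpectedProfile:
    """Mean balanced contact per bin distance and the log10-distance
    frequency density of cis contacts."""
    if matrix.balanced is None:
        raise ValueError("balanced layer required; run ice_balance first")
    res = matrix.bins.resolution
    expected = {}
    dist_bp = []
    dist_weight = []
    for c in matrix.bins.chroms:
        N = matrix.balanced[c]
        unm = ~matrix.mask[c]
        n = N.shape[0]
        e = np.full(n, np.nan)
        for s in range(n):
            d = np.diagonal(N, offset=s)
            valid = unm[: n - s] & unm[s:]
            cnt = int(valid.sum())
            if cnt > 0:
                e[s] = d.sum() / cnt
                if s > 0:
                    dist_bp.append(s * res)
                    dist_weight.append(d.sum())
        expected[c] = e
    lo = np.log10(res) if not dist_bp else np.floor(np.log10(min(dist_bp)) / density_binwidth) * density_binwidth
    hi = lo + density_binwidth if not dist_bp else np.ceil(np.log10(max(dist_bp)) / density_binwidth) * density_binwidth + density_binwidth
    edges = np.arange(lo, hi + density_binwidth / 2, density_binwidth)
    w = np.asarray(dist_weight, dtype=float)
    hist, edges = np.histogram(np.log10(dist_bp) if dist_bp else [], bins=edges, weights=w)
    total = hist.sum()
    dens = hist / total if total > 0 else hist
    density = pd.DataFrame({"log10_lo": edges[:-1], "log10_hi": edges[1:],
                            "density": dens})
    return ExpectedProfile(res, expected, density)


def oe_transform(matrix: ContactMatrix) -> ContactMatrix:
    """Observed/expected layer: Z_ij = N_ij / E(|i-j|); undefined E masks Z."""
    prof = expected_profile(matrix)
    oe = {}
    for c in matrix.bins.chroms:
        N = matrix.balanced[c]
        e = prof.expected[c]
        n = N.shape[0]
        i, j = np.indices((n, n), sparse=True)
        Es = e[np.abs(i - j)]
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = np.where(np.isfinite(Es) & (Es > 0), N / Es, 0.0)
        Z[matrix.mask[c], :] = 0.0
        Z[:, matrix.mask[c]] = 0.0
        oe[c] = Z
    matrix.oe = oe
    return matrix


def export_dense(matrix: ContactMatrix, chrom: str, path, layer: str = "raw") -> None:
    """Tab-delimited dense export of one chromosome's matrix (small inputs)."""
    data = getattr(matrix, layer)
    np.savetxt(path, data[chrom], delimiter="\t", fmt="%.10g")


def bias_bedgraph(matrix: ContactMatrix) -> pd.DataFrame:
    if matrix.bias is None:
        raise ValueError("no bias vector; run ice_balance first")
    frames = []
    bf = matrix.bins.bins_frame()
    vals = np.concatenate([matrix.bias[c] for c in matrix.bins.chroms])
    bf = bf.drop(columns="bin_id")
    bf["value"] = vals
    return bf
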