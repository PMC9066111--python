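"""Synthetic genome, contact-map, MeDIP and ChIP-peak simulator with planted
ground truth.

The generator emits a desk-scale genome (default: two 20-Mb chromosomes,
200 genes each) carrying every structure the downstream pipeline claims to
detect, and records the planted truth so recovery can be scored:

* megabase-scale A/B compartment blocks on the 500-kb grid, interacting with
  contrast ``delta`` (same-compartment pairs enriched ``1+delta``, opposite
  depleted ``1-delta``);
* adjacent TAD domains on the 40-kb grid with within-domain enrichment
  ``gamma`` and per-boundary insulation factors ``f`` in (0, 1] — the
  fraction of cross-boundary expected contacts retained, applied
  multiplicatively per crossed boundary;
* a power-law distance decay ``P(s) ~ s**-alpha`` between bin centers, with a
  separate fixed diagonal intensity;
* per-bin multiplicative biases (log-normal, stored on the 20-kb base grid);
* Poisson count noise at a configured per-replicate sequencing depth;
* hyper/hypo-methylated regions over a MeDIP baseline with a TSS methylation
  dip and a TES rise;
* ChIP peaks placed at boundaries, promoters, or uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contact import BinTable, ContactMatrix
from . import io as cio

log = logging.getLogger("chromarch")

BIAS_GRID = 20_000   # finest common grid of the 500/40/20-kb resolutions
TAD_GRID = 40_000


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study. Defaults define the study conditions."""

    decay_exponent: float = 1.0          # alpha in P(s) ~ s**-alpha
    compartment_contrast: float = 0.4    # delta in [0, 1)
    tad_enrichment: float = 3.0          # gamma >= 1, within-domain multiplier
    insulation: float = 0.8              # default boundary retention factor f
    sequencing_depth: float = 5e6        # expected cis contacts per replicate
    replicate_count: int = 2             # per condition, matching the Hi-C design
    diag_factor: float = 2.0             # diagonal intensity / s=resolution decay
    bias_sigma: float = 0.2              # log-normal sd of per-bin biases

    chrom_length: int = 20_000_000
    n_chroms: int = 2
    genes_per_chrom: int = 200
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    gene_density_ratio: float = 3.0      # A-compartment / B-compartment gene density

    compartment_block_bins: tuple[int, int] = (2, 6)    # 500-kb bins per block
    tad_size_range: tuple[int, int] = (400_000, 1_600_000)

    medip_depth: float = 2e6             # expected MeDIP counts per replicate
    medip_window: int = 1_000
    tss_dip_depth: float = 0.6
    tss_dip_sigma: float = 1_000.0
    tes_rise: float = 0.8
    tes_rise_sigma: float = 2_000.0
    n_hyper_dmrs: int = 20
    n_hypo_dmrs: int = 10
    dmr_width: int = 5_000
    dmr_fold_change: float = 4.0

    # treated-condition deltas: the planted effects of the perturbation
    treated_tad_enrichment: float = 2.0   # reduced within-domain enrichment
    switch_a_to_b: float = 0.05           # genome fraction flipped A->B
    switch_b_to_a: float = 0.03           # genome fraction flipped B->A
    diff_block_count: int = 1
    diff_block_size: int = 1_000_000
    diff_block_fold: float = 4.0          # interaction fold change in treated

    peak_count: tuple[int, int, int] = (50, 100, 50)    # boundary, promoter, random
    peak_width_range: tuple[int, int] = (200, 500)
    boundary_peak_jitter: float = 20_000.0
    boundary_peak_max_offset: int = TAD_GRID             # +-1 bin at 40 kb
    promoter_peak_halfwidth: int = 1_000

    def validate(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not (0.0 <= self.compartment_contrast < 1.0):
            raise ValueError("compartment_contrast must be in [0, 1)")
        if self.tad_enrichment < 1.0:
            raise ValueError("tad_enrichment must be >= 1")
        if not (0.0 < self.insulation <= 1.0):
            raise ValueError("insulation must be in (0, 1]")
        if self.sequencing_depth <= 0 or self.medip_depth <= 0:
            raise ValueError("depths must be > 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if abs(np.log2(self.dmr_fold_change)) < 1.0:
            raise ValueError("planted DMRs need |log2 fold change| >= 1")
        if self.chrom_length % 500_000:
            raise ValueError("chromosome length must be a multiple of 500 kb")


@dataclass
class SyntheticGenome:
    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame          # BED12
    seed: int

    @property
    def chromsizes(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class SyntheticTruth:
    """Planted structure, the recovery oracle for every downstream stage."""

    compartment_labels: pd.DataFrame     # chrom, start, end, label (500-kb bins)
    tad_domains: pd.DataFrame            # chrom, start, end (adjacent, sorted)
    boundary_insulation: pd.DataFrame    # chrom, pos, f
    planted_dmrs: pd.DataFrame           # chrom, start, end, direction, fold
    bias_profile: pd.DataFrame           # chrom, start, end, bias (20-kb grid)
    peak_truth: pd.DataFrame | None = None

    def validate(self) -> None:
        d = self.tad_domains.sort_values(["chrom", "start"])
        for chrom, g in d.groupby("chrom", sort=False):
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"{chrom}: overlapping planted domains")
        f = self.boundary_insulation["f"].to_numpy()
        if ((f <= 0) | (f > 1)).any():
            raise ValueError("insulation factors must lie in (0, 1]")
        if len(self.planted_dmrs):
            lfc = np.abs(np.log2(self.planted_dmrs["fold"].to_numpy(dtype=float)))
            if (lfc < 1.0 - 1e-12).any():
                raise ValueError("every planted DMR needs |log2 fold change| >= 1")


def simulate_genome(config: SimulationConfig | None = None,
                    seed: int = 0) -> tuple[SyntheticGenome, SyntheticTruth]:
    """Build the toy genome and plant all truth structures."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]

    comp_rows, dom_rows, bnd_rows, bias_rows = [], [], [], []
    for name, length in chroms:
        # A/B blocks on the 500-kb grid, alternating, random Mb-scale lengths
        nbins = length // 500_000
        label = "A" if rng.random() < 0.5 else "B"
        b = 0
        while b < nbins:
            w = int(rng.integers(config.compartment_block_bins[0],
                                 config.compartment_block_bins[1] + 1))
            w = min(w, nbins - b)
            for k in range(w):
                comp_rows.append((name, (b + k) * 500_000, (b + k + 1) * 500_000, label))
            label = "B" if label == "A" else "A"
            b += w

        # adjacent TADs on the 40-kb grid
        lo = config.tad_size_range[0] // TAD_GRID
        hi = config.tad_size_range[1] // TAD_GRID
        pos = 0
        edges = [0]
        while pos < length:
            w = int(rng.integers(lo, hi + 1)) * TAD_GRID
            pos = min(pos + w, length)
            edges.append(pos)
        if len(edges) > 2 and edges[-1] - edges[-2] < config.tad_size_range[0]:
            del edges[-2]  # merge a short final fragment into the last domain
        for s, e in zip(edges[:-1], edges[1:]):
            dom_rows.append((name, s, e))
        for p in edges[1:-1]:
            bnd_rows.append((name, p, config.insulation))

        nb = length // BIAS_GRID
        logb = rng.normal(0.0, config.bias_sigma, nb)
        logb -= logb.mean()  # geometric mean 1
        starts = np.arange(nb) * BIAS_GRID
        for s, v in zip(starts, np.exp(logb)):
            bias_rows.append((name, int(s), int(s) + BIAS_GRID, float(v)))

    comp = pd.DataFrame(comp_rows, columns=["chrom", "start", "end", "label"])
    doms = pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])
    bnds = pd.DataFrame(bnd_rows, columns=["chrom", "pos", "f"])
    bias = pd.DataFrame(bias_rows, columns=["chrom", "start", "end", "bias"])

    genes = _place_genes(chroms, comp, config, rng)
    dmrs = _place_dmrs(chroms, config, rng)

    truth = SyntheticTruth(comp, doms, bnds, dmrs, bias)
    truth.validate()
    return SyntheticGenome(chroms, genes, seed), truth


def _place_genes(chroms, comp: pd.DataFrame, config: SimulationConfig,
                 rng) -> pd.DataFrame:
    rows = []
    gid = 0
    ratio = config.gene_density_ratio
    for name, length in chroms:
        blocks = comp[comp["chrom"] == name]
        w = np.where(blocks["label"].to_numpy() == "A", ratio, 1.0)
        w = w / w.sum()
        margin = 20_000
        for _ in range(config.genes_per_chrom):
            bi = rng.choice(len(blocks), p=w)
            bs, be = blocks.iloc[bi][["start", "end"]]
            tss = int(rng.integers(bs, be))
            glen = int(rng.integers(*config.gene_length_range))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = tss, tss + glen
            else:
                start, end = tss - glen, tss
            start = max(margin, min(start, length - margin - glen))
            end = start + glen
            nex = int(rng.integers(1, 6))
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * nex - 2,
                                      replace=False)) if nex > 1 else np.array([], int)
            edges = np.concatenate([[0], cuts, [glen]])
            bstarts = edges[0::2][:nex]
            bends = edges[1::2][:nex]
            bends = np.append(bends, glen)[:nex]
            sizes = bends - bstarts
            rows.append((name, start, end, f"gene{gid:05d}", 0, strand,
                         start, end, "0", nex,
                         ",".join(str(int(s)) for s in sizes) + ",",
                         ",".join(str(int(s)) for s in bstarts) + ","))
            gid += 1
    return pd.DataFrame(rows, columns=cio.BED12_COLS)


def _place_dmrs(chroms, config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    win = config.medip_window
    wwin = config.dmr_width // win
    sep = 4  # windows of clearance between planted regions
    specs = [("hyper", config.dmr_fold_change)] * config.n_hyper_dmrs + \
            [("hypo", config.dmr_fold_change)] * config.n_hypo_dmrs
    per_chrom = np.array_split(np.arange(len(specs)), len(chroms))
    for (name, length), idxs in zip(chroms, per_chrom):
        taken: list[tuple[int, int]] = []
        nwin = length // win
        for k in idxs:
            for _ in range(1000):
                s = int(rng.integers(1, nwin - wwin - 1))
                if all(s + wwin + sep <= a or s >= b + sep for a, b in taken):
                    taken.append((s, s + wwin))
                    direction, fold = specs[k]
                    rows.append((name, s * win, (s + wwin) * win, direction, fold))
                    break
            else:
                raise RuntimeError("could not place all DMRs without overlap")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "fold"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# contact maps

def _bin_factors(genome: SyntheticGenome, truth: SyntheticTruth, chrom: str,
                 resolution: int):
    """Per-bin compartment label index, domain index, boundary crossing logs
    and bias, all evaluated at bin centers."""
    length = genome.chromsizes[chrom]
    n = length // resolution
    centers = (np.arange(n) + 0.5) * resolution

    comp = truth.compartment_labels[truth.compartment_labels["chrom"] == chrom]
    lab = (comp["label"].to_numpy() == "A").astype(np.int8)
    bin_lab = lab[np.searchsorted(comp["start"].to_numpy(), centers, "right") - 1]

    doms = truth.tad_domains[truth.tad_domains["chrom"] == chrom]
    dom_idx = np.searchsorted(doms["start"].to_numpy(), centers, "right") - 1
    # centers beyond a domain's end belong to no domain (index -1)
    ends = doms["end"].to_numpy()
    valid = (dom_idx >= 0) & (centers < ends[np.clip(dom_idx, 0, None)])
    dom_idx = np.where(valid, dom_idx, -1)

    bnd = truth.boundary_insulation[truth.boundary_insulation["chrom"] == chrom]
    p = bnd["pos"].to_numpy(dtype=float)
    logf = np.concatenate([[0.0], np.cumsum(np.log(bnd["f"].to_numpy(dtype=float)))])
    cross_idx = np.searchsorted(p, centers)

    bias = truth.bias_profile[truth.bias_profile["chrom"] == chrom]["bias"].to_numpy()
    if resolution >= BIAS_GRID:
        k = resolution // BIAS_GRID
        b = np.exp(np.log(bias[: n * k]).reshape(n, k).mean(axis=1))
    else:
        rep = BIAS_GRID // resolution
        b = np.repeat(bias, rep)[:n]
    return n, bin_lab, dom_idx, logf, cross_idx, b


def _check_alignment(truth: SyntheticTruth, resolution: int) -> None:
    if resolution <= TAD_GRID:
        for _, row in truth.tad_domains.iterrows():
            if row["start"] % resolution or row["end"] % resolution:
                raise ValueError(
                    f"planted domain {row['chrom']}:{row['start']}-{row['end']} "
                    f"is not aligned to the {resolution}-bp grid")


def _block_factor(chrom: str, n: int, resolution: int,
                  extra_blocks: pd.DataFrame | None) -> np.ndarray | None:
    """Multiplicative factor for planted interaction blocks (both bin
    centers inside the same block row)."""
    if extra_blocks is None or extra_blocks.empty:
        return None
    blocks = extra_blocks[extra_blocks["chrom"] == chrom]
    if blocks.empty:
        return None
    centers = (np.arange(n) + 0.5) * resolution
    B = np.ones((n, n))
    for _, r in blocks.iterrows():
        inside = (centers >= r["start"]) & (centers < r["end"])
        B[np.ix_(inside, inside)] *= float(r["fold"])
    return B


def _intensity_matrix(genome, truth, config: SimulationConfig, chrom: str,
                      resolution: int, with_bias: bool = True,
                      extra_blocks: pd.DataFrame | None = None) -> np.ndarray:
    """Unscaled expected intensity: s**-alpha * c * t * f (* b_i b_j)."""
    n, lab, dom, logf, cidx, bias = _bin_factors(genome, truth, chrom, resolution)
    i = np.arange(n)
    s = np.abs(i[:, None] - i[None, :]) * float(resolution)
    with np.errstate(divide="ignore"):
        D = np.where(s > 0, s ** -config.decay_exponent,
                     config.diag_factor * float(resolution) ** -config.decay_exponent)
    d = config.compartment_contrast
    C = np.where(lab[:, None] == lab[None, :], 1.0 + d, 1.0 - d)
    same_dom = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
    T = np.where(same_dom, config.tad_enrichment, 1.0)
    F = np.exp(-np.abs(logf[cidx][:, None] - logf[cidx][None, :]))
    U = D * C * T * F
    B = _block_factor(chrom, n, resolution, extra_blocks)
    if B is not None:
        U *= B
    if with_bias:
        U *= np.outer(bias, bias)
    return U


def expected_intensity(genome, truth, config: SimulationConfig,
                       resolution: int,
                       extra_blocks: pd.DataFrame | None = None) -> dict[str, np.ndarray]:
    """Per-chromosome expected count matrix lambda, scaled to the configured
    per-replicate depth. Independent of the Poisson sampler; used as the
    noise-free oracle."""
    _check_alignment(truth, resolution)
    U = {c: _intensity_matrix(genome, truth, config, c, resolution,
                              extra_blocks=extra_blocks)
         for c, _ in genome.chromosomes}
    total = sum(np.triu(m).sum() for m in U.values())
    K = config.sequencing_depth / total
    return {c: K * m for c, m in U.items()}


def structural_oe_matrix(genome, truth, config: SimulationConfig,
                         resolution: int) -> dict[str, np.ndarray]:
    """Analytic observed/expected structure: the c*t*f factor table with the
    distance decay and biases divided out. This is what an ideal O/E
    transform would recover; boundary-strength calibration runs on it."""
    _check_alignment(truth, resolution)
    out = {}
    for c, _ in genome.chromosomes:
        n, lab, dom, logf, cidx, _ = _bin_factors(genome, truth, c, resolution)
        d = config.compartment_contrast
        C = np.where(lab[:, None] == lab[None, :], 1.0 + d, 1.0 - d)
        same_dom = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
        T = np.where(same_dom, config.tad_enrichment, 1.0)
        F = np.exp(-np.abs(logf[cidx][:, None] - logf[cidx][None, :]))
        out[c] = C * T * F
    return out


def simulate_contact_map(genome: SyntheticGenome, truth: SyntheticTruth,
                         config: SimulationConfig, resolution: int,
                         seed: int,
                         extra_blocks: pd.DataFrame | None = None) -> ContactMatrix:
    """Draw one replicate's raw cis contact matrix at a resolution.

    Expected intensity per pair: lambda_ij = depth-scale * s**-alpha * c_ij *
    t_ij * f_ij * b_i * b_j, with c the compartment factor, t the
    within-domain enrichment, f the product of insulation factors of planted
    boundaries strictly between the bin centers, and b the bias vector.
    Counts are Poisson; the matrix is exactly symmetric.
    """
    config.validate()
    for c, length in genome.chromosomes:
        if length % resolution:
            raise ValueError(f"resolution {resolution} does not divide {c}")
    lam = expected_intensity(genome, truth, config, resolution, extra_blocks)
    rng = np.random.default_rng(seed)
    raw = {}
    for c, _ in genome.chromosomes:
        m = lam[c]
        upper = np.triu(rng.poisson(m).astype(float))
        raw[c] = upper + np.triu(upper, 1).T
    bins = BinTable(genome.chromsizes, resolution)
    return ContactMatrix(bins, raw)


def treated_condition(genome: SyntheticGenome, truth: SyntheticTruth,
                      config: SimulationConfig, seed: int
                      ) -> tuple[SyntheticTruth, SimulationConfig, pd.DataFrame]:
    """Derive the treated condition's truth from the control truth.

    Planted treatment effects: a configured genome fraction of 500-kb bins
    flips A->B and B->A; within-domain enrichment drops to
    ``treated_tad_enrichment``; and ``diff_block_count`` random Mb-scale
    blocks gain a ``diff_block_fold`` interaction increase (returned
    separately so the differential caller can be scored against them)."""
    from dataclasses import replace
    rng = np.random.default_rng(seed)
    comp = truth.compartment_labels.copy()
    lab = comp["label"].to_numpy().copy()
    n = len(lab)
    a_idx = np.flatnonzero(lab == "A")
    b_idx = np.flatnonzero(lab == "B")
    n_ab = min(int(round(config.switch_a_to_b * n)), len(a_idx))
    n_ba = min(int(round(config.switch_b_to_a * n)), len(b_idx))
    lab[rng.choice(a_idx, size=n_ab, replace=False)] = "B"
    lab[rng.choice(b_idx, size=n_ba, replace=False)] = "A"
    comp["label"] = lab

    blocks = []
    grid = BIAS_GRID
    for _ in range(config.diff_block_count):
        c, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        lo = length // 4
        hi = 3 * length // 4 - config.diff_block_size
        start = int(rng.integers(lo // grid, hi // grid + 1)) * grid
        blocks.append((c, start, start + config.diff_block_size,
                       config.diff_block_fold))
    diff_blocks = pd.DataFrame(blocks, columns=["chrom", "start", "end", "fold"])

    truth_t = SyntheticTruth(comp, truth.tad_domains.copy(),
                             truth.boundary_insulation.copy(),
                             truth.planted_dmrs.copy(),
                             truth.bias_profile.copy(), truth.peak_truth)
    cfg_t = replace(config, tad_enrichment=config.treated_tad_enrichment)
    return truth_t, cfg_t, diff_blocks


# ---------------------------------------------------------------------------
# MeDIP tracks

def medip_intensity(genome: SyntheticGenome, truth: SyntheticTruth,
                    config: SimulationConfig, window: int) -> dict[str, dict[str, np.ndarray]]:
    """Unscaled expected MeDIP intensity per window, per condition.

    Baseline 1 with a multiplicative Gaussian dip at each TSS and rise at
    each TES; planted DMRs multiply the treated condition only (hyper: *fold,
    hypo: /fold)."""
    for c, length in genome.chromsizes.items():
        if length % window:
            raise ValueError(f"window {window} does not divide {c}")
    if len(truth.planted_dmrs):
        bad = truth.planted_dmrs[(truth.planted_dmrs["start"] % window != 0) |
                                 (truth.planted_dmrs["end"] % window != 0)]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(f"planted DMR {r['chrom']}:{r['start']}-{r['end']} "
                             f"is not aligned to the {window}-bp window grid")
    tss = cio.gene_tss(genome.genes)
    tes = cio.gene_tes(genome.genes)
    gchrom = genome.genes["chrom"].to_numpy()
    out = {"control": {}, "treated": {}}
    for c, length in genome.chromsizes.items():
        n = length // window
        centers = (np.arange(n) + 0.5) * window
        base = np.ones(n)
        for anchor, scale, sigma, sign in (
                (tss[gchrom == c], config.tss_dip_depth, config.tss_dip_sigma, -1.0),
                (tes[gchrom == c], config.tes_rise, config.tes_rise_sigma, +1.0)):
            for a in anchor:
                lo = max(0, int((a - 4 * sigma) // window))
                hi = min(n, int((a + 4 * sigma) // window) + 1)
                x = centers[lo:hi]
                base[lo:hi] *= 1.0 + sign * scale * np.exp(-(x - a) ** 2 / (2 * sigma ** 2))
        treated = base.copy()
        dmrs = truth.planted_dmrs[truth.planted_dmrs["chrom"] == c]
        for _, r in dmrs.iterrows():
            sel = (centers >= r["start"]) & (centers < r["end"])
            fold = float(r["fold"])
            treated[sel] *= fold if r["direction"] == "hyper" else 1.0 / fold
        out["control"][c] = base
        out["treated"][c] = treated
    return out


@dataclass
class MethylationTrack:
    """Fixed-width window counts per condition and replicate."""

    windows: BinTable
    counts: dict[str, list[np.ndarray]]   # condition -> per-replicate global arrays

    def library_size(self, condition: str, rep: int) -> float:
        return float(self.counts[condition][rep].sum())

    def window_frame(self) -> pd.DataFrame:
        return self.windows.bins_frame().drop(columns="bin_id")


def simulate_medip_tracks(genome, truth, config: SimulationConfig,
                          window: int, seed: int) -> MethylationTrack:
    config.validate()
    inten = medip_intensity(genome, truth, config, window)
    rng = np.random.default_rng(seed)
    windows = BinTable(genome.chromsizes, window)
    counts: dict[str, list[np.ndarray]] = {}
    for cond in ("control", "treated"):
        flat = np.concatenate([inten[cond][c] for c in windows.chroms])
        lam = flat * (config.medip_depth / flat.sum())
        counts[cond] = [rng.poisson(lam).astype(np.int64)
                        for _ in range(config.replicate_count)]
    return MethylationTrack(windows, counts)


# ---------------------------------------------------------------------------
# peaks

def simulate_peaks(genome: SyntheticGenome, truth: SyntheticTruth,
                   config: SimulationConfig, seed: int) -> pd.DataFrame:
    """narrowPeak frame with boundary-, promoter- and random-class peaks.

    Boundary peaks are centered within +-1 bin (40 kb) of a planted boundary
    (truncated-Gaussian jitter); promoter peaks within +-1 kb of a TSS;
    random peaks uniform over the genome. Placement classes are recorded in
    ``truth.peak_truth``."""
    config.validate()
    n_bnd, n_prom, n_rand = config.peak_count
    if min(config.peak_count) < 0:
        raise ValueError("peak counts must be >= 0")
    if n_bnd > 0 and truth.boundary_insulation.empty:
        raise ValueError("boundary-class peaks requested but truth has no boundaries")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromsizes)
    lengths = np.array([genome.chromsizes[c] for c in chroms], dtype=float)
    tss = cio.gene_tss(genome.genes)
    gchrom = genome.genes["chrom"].to_numpy()

    rows, truth_rows = [], []

    def add(chrom, center, klass, idx):
        width = int(rng.integers(config.peak_width_range[0],
                                 config.peak_width_range[1] + 1))
        start = int(max(0, min(center - width // 2,
                               genome.chromsizes[chrom] - width)))
        end = start + width
        summit = int(center) - start
        summit = max(0, min(summit, width - 1))
        rows.append((chrom, start, end, f"peak{idx:05d}",
                     int(rng.integers(200, 1000)), ".",
                     round(float(rng.uniform(2, 20)), 4), -1.0, -1.0, summit))
        truth_rows.append((chrom, start, end, klass))

    idx = 0
    bnd = truth.boundary_insulation
    for _ in range(n_bnd):
        r = bnd.iloc[int(rng.integers(len(bnd)))]
        off = np.clip(rng.normal(0.0, config.boundary_peak_jitter),
                      -config.boundary_peak_max_offset,
                      config.boundary_peak_max_offset)
        add(r["chrom"], int(r["pos"] + off), "boundary", idx)
        idx += 1
    for _ in range(n_prom):
        g = int(rng.integers(len(genome.genes)))
        off = int(rng.integers(-config.promoter_peak_halfwidth,
                               config.promoter_peak_halfwidth + 1))
        add(gchrom[g], int(tss[g] + off), "promoter", idx)
        idx += 1
    for _ in range(n_rand):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        add(chroms[ci], int(rng.integers(0, lengths[ci])), "random", idx)
        idx += 1

    peaks = pd.DataFrame(rows, columns=cio.NARROWPEAK_COLS)
    truth.peak_truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "class"])
    return peaks


# ---------------------------------------------------------------------------
# truth export / import

def write_truth(genome: SyntheticGenome, truth: SyntheticTruth, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_keyvalue({c: l for c, l in genome.chromosomes},
                       outdir / "chromsizes.tsv")
    cio.write_bed12(genome.genes, outdir / "genes.bed12")
    cio.write_bed(truth.compartment_labels, outdir / "truth_compartments.bed")
    cio.write_bed(truth.tad_domains.assign(name="domain"),
                  outdir / "truth_domains.bed")
    cio.write_table(truth.boundary_insulation, outdir / "truth_boundaries.tsv")
    cio.write_table(truth.planted_dmrs, outdir / "truth_dmrs.tsv")
    cio.write_bedgraph(truth.bias_profile.rename(columns={"bias": "value"}),
                       outdir / "truth_bias.bedGraph")
    if truth.peak_truth is not None:
        cio.write_bed(truth.peak_truth, outdir / "truth_peaks.bed")


def read_truth(outdir) -> tuple[dict[str, int], SyntheticTruth]:
    from pathlib import Path
    outdir = Path(outdir)
    sizes = {k: int(v) for k, v in cio.read_keyvalue(outdir / "chromsizes.tsv").items()}
    comp = cio.read_bed(outdir / "truth_compartments.bed",
                        names=["chrom", "start", "end", "label"])
    doms = cio.read_bed(outdir / "truth_domains.bed",
                        names=["chrom", "start", "end", "name"])[["chrom", "start", "end"]]
    bnds = cio.read_table(outdir / "truth_boundaries.tsv")
    dmrs = cio.read_table(outdir / "truth_dmrs.tsv")
    bias = cio.read_bedgraph(outdir / "truth_bias.bedGraph").rename(
        columns={"value": "bias"})
    pt = None
    peaks_path = outdir / "truth_peaks.bed"
    if peaks_path.exists():
        pt = cio.read_bed(peaks_path, names=["chrom", "start", "end", "class"])
    return sizes, SyntheticTruth(comp, doms, bnds, dmrs, bias, pt)


def config_echo(config: SimulationConfig) -> dict:
    return {k: v for k, v in asdict(config).items()}
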