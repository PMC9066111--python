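# Methods

## Scope and data model

The pipeline operates on binned cis contact matrices (one dense symmetric
matrix per chromosome; trans contacts are ignored throughout), ChIP peaks
(narrowPeak), gene models (BED12) and MeDIP window counts (bedGraph). Three
Hi-C resolutions are used, each for the analysis it suits: 500 kb for A/B
compartments, 40 kb for TAD calling, 20 kb for differential interactions.
Coordinates are 0-based half-open everywhere except the HiC-Pro triplet
dialect, whose bin IDs are 1-based; both conventions are enforced at the
parsers to prevent off-by-one drift.

## ICE normalization

Iterative correction removes multiplicative per-bin biases: each iteration
rescales rows and columns by the square root of their marginal sums
(renormalized to mean one) until the coefficient of variation of unmasked
row sums falls below `tol` (default 1e-5; `max_iter` 200). The square-root
damping is what makes the symmetric iteration converge monotonically —
dividing by the full marginal ratio overshoots and oscillates on small
heterogeneous matrices. The lowest 2% of bins by raw coverage (plus
zero-coverage bins) are masked first. The bias vector is normalized to
geometric mean one over unmasked bins so the balanced layer keeps the raw
count scale, making intra-TAD means comparable across conditions after
depth scaling. On an exactly balanceable matrix the recovered bias is
proportional to the planted corruption to ~1e-9 at `tol = 1e-9`.

## Distance decay and O/E

`E(s)` is the mean balanced contact over unmasked pairs at bin distance `s`,
per chromosome; the observed/expected layer is `Z_ij = N_ij / E(|i−j|)`.
The contact frequency density is accumulated over log10(bp) bins of width
0.1 and sums to one. The decay exponent is fit by least squares on
log10 E(s) vs log10 s over 200 kb–5 Mb; this recovers the generator's α on
structureless simulations. On structured maps the fitted slope is steeper
than α because domain insulation accumulates with distance — that is a
property of the data, not the fit.

## Compartments

PC1 is the leading eigenvector of the per-chromosome Pearson correlation
matrix of the O/E map at 500 kb (the Lieberman-Aiden convention; the
correlation-matrix form is adopted where a tool is unspecified). The first
two diagonals are excluded from the correlation (pairwise-complete): on
desk-scale chromosomes the near-diagonal band is dominated by domain
structure, which otherwise drags PC1 toward a positional gradient; the
exclusion mirrors what production compartment callers do. Sign is oriented
per chromosome so the gene-dense half of bins (by TSS count, ties stable)
has positive mean PC1 — A is the open, gene-dense compartment. PC1 of
exactly zero is treated as masked rather than tie-broken. Switching classes
(A→A, B→B, A→B, B→A) are assigned per bin over bins unmasked in both
conditions, and their fractions sum to one.

## TAD calling

The directionality index per 40-kb bin contrasts upstream (A) and
downstream (B) balanced contact sums within a 2-Mb window (50 bins):

    E = (A + B) / 2
    DI = sign(B − A) · [ (A − E)² / E + (B − E)² / E ]

Bins within a window of the chromosome edge are computed over the available
span and flagged partial; bins with A + B = 0 get DI = 0. A 3-state
Gaussian HMM (upstream-biased / unbiased / downstream-biased) is fit by EM
on the pooled genome — quantile-based mean initialization (10/50/90th
percentiles), sticky transition prior, tol 1e-4, ≤ 200 iterations, fixed
seed 13 — then relabeled by ordered means and Viterbi-decoded per
chromosome. A failed or degenerate fit is retried once with perturbed
initialization. A domain opens at the first bin of a downstream-biased run
and closes at the last bin of the next upstream-biased run. Gaps between
consecutive domains shorter than 400 kb are boundaries; longer gaps are
unorganized chromatin; zero-length gaps yield a 1-bp boundary at the shared
edge. Boundary recall against planted truth counts a planted position as
recovered when a called boundary midpoint (floored) lies within ±1 bin.

## Boundary strength

For a boundary whose region overlaps bins `bs..be`, with flank `w` (default
10 bins = 400 kb at 40 kb): left block `L = [bs−w, bs)`, right block
`R = [be+1, be+1+w)`, and

    S = log2( mean(Z over L×L ∪ R×R) / mean(Z over L×R) )

Higher S = stronger insulation. Boundaries within `w` bins of a chromosome
edge are left unscored. The score is calibrated: on the noise-free
structural O/E of an isolated boundary retaining a fraction `f` of
cross-boundary contacts (no domain enrichment), `S = −log2(f)` exactly,
because every cross-block pair carries factor `f` and every intra-block
pair factor 1. On an O/E computed from a matrix that itself contains the
boundary, the depletion leaks into `E(s)` at the percent level, so the
calibration is stated against the structural table. Cross-condition
boundary matching uses ≥ 1 bp overlap of boundary regions; a boundary is
"bound" when ≥ 1 peak overlaps it; group comparisons are two-sided
Mann-Whitney and are skipped (with a log entry) when a group is empty.

## Intra-TAD interaction and TAD compartment scores

Per-TAD interaction is the mean off-diagonal O/E over unmasked bins inside
the domain (domains spanning < 3 usable bins are skipped). Condition
comparisons report the median difference and a two-sided Mann-Whitney p,
each condition scored on its own called TADs. The TAD compartment score is
the mean PC1 over 500-kb bins whose midpoints fall inside the domain
(positive = A, negative = B, zero or no bins = unscored); switching is
evaluated over TAD pairs matched by ≥ 50% reciprocal overlap.

## Differential interactions

At 20 kb, replicates are summed per condition and library sizes are the
total cis counts. Pairs with summed raw count < 10 across all samples are
untestable and excluded. Each remaining pair is tested with a two-sided
exact binomial test of the treated count against the pooled total under the
null proportion `s_t/(s_t+s_c)`; BH correction runs over tested pairs.
`log2FC = log2((x_t+0.5)/s_t) − log2((x_c+0.5)/s_c)` (the log-difference
form makes condition swap negate it bitwise). Significance: q < 0.05 and
|log2FC| > 1. With two replicates per condition a pooled exact test is the
defensible default — there are not enough replicates to estimate
dispersion — so replicate concordance (Pearson r of raw upper-triangle
counts) is reported as a diagnostic instead of entering the test. The exact
test's type-I error at nominal 0.05 is ≤ 0.05 by construction (discreteness
makes it conservative, empirically ≈ 0.04). The binomial p-value is the
minimum-likelihood two-sided definition, computed vectorized with a binary
search on the monotone flank of the pmf, and verified against the scalar
reference implementation.

## Methylation

MeDIP is enrichment-based, so methylation is modeled as window counts
(default 1 kb), not CpG-level calls. DMR calling reuses the binomial engine
per window (pooled replicates, library-size null, BH); windows at q < 0.05
and |log2FC| > 1 merge when within 1 kb and of the same direction — 
opposite directions never merge. Direction is relative to the treated
condition (hyper ⇔ log2FC > 0); region log2FC is recomputed from summed
member-window counts. The metagene profile is 50 upstream-flank + 100
scaled gene-body + 50 downstream-flank bins (fixed 200), strand-oriented,
library-size normalized and averaged over replicates, integrating the
window track exactly over each profile bin via a cumulative integral; genes
shorter than 100 bp are skipped. DMR feature annotation is by midpoint with
precedence promoter (TSS ± 2 kb, a flag) > exon > intron > intergenic, so
the composition sums to one and is checkable by brute force.

## Peak integration

Peaks are anchored at their narrowPeak summit (midpoint fallback). The
nearest-TSS distance is signed by gene strand (negative = upstream); ties
break toward the smaller coordinate. Distance classes default to promoter
≤ 2 kb, proximal ≤ 10 kb, distal beyond — the thresholds are parameters
since the field has no single convention. Boundary enrichment counts peak
summits per 25-kb step across ±0.5 Mb around boundary midpoints, normalized
per boundary, excluding boundaries truncated by chromosome edges. All
overlap operations use the ≥ 1 bp rule and agree exactly with quadratic
scans on randomized fixtures.

## Synthetic data generator

The generator emulates a two-condition perturbation study at desk scale.
Defaults: two 20-Mb chromosomes; 200 genes per chromosome (2–10 kb, 1–5
exons), placed with 3× higher density in A blocks; A/B blocks of 1–3 Mb on
the 500-kb grid with contrast δ = 0.4; adjacent TADs of 0.4–1.6 Mb on the
40-kb grid (≥ 15 per chromosome) with within-domain enrichment γ = 3;
log-normal per-bin biases (σ = 0.2) stored on the 20-kb base grid (coarser
bins take the geometric mean of their constituents); Poisson counts at
5×10⁶ expected cis contacts per replicate, two replicates per condition.
The depth is chosen for statistical power at this genome size — the source
study reports only a genome-wide total on a full mammalian genome — and the
two-replicate design matches that study's Hi-C layout.

Expected intensity per pair: λ_ij = depth-scale · s^−α · c_ij · t_ij ·
f_ij · b_i b_j, with s the bin-center distance (α = 1), c the compartment
factor (1±δ), t the domain factor (γ inside a domain), f the product of
insulation factors of boundaries strictly between the centers, and b the
bias. The diagonal uses a separate fixed intensity (2× the one-bin decay
value) and is excluded from decay fitting, avoiding the s^−α singularity.
The per-crossed-boundary insulation model composes multiplicatively, which
lets monotonicity tests vary one boundary at a time — but it also means the
default retention factor must stay mild: with ~20 boundaries per
chromosome, f = 0.8 already attenuates 10-Mb contacts several-fold, which
is at the edge of what real P(s) curves show; stronger defaults would
extinguish long-range counts entirely, something no real map does. Strong
boundaries (f = 0.2–0.3) are therefore exercised explicitly in
boundary-focused analyses rather than genome-wide.

The treated condition derives from the control truth: 5% of 500-kb bins
flip A→B and 3% B→A, within-domain enrichment drops to γ = 2, and one 1-Mb
block gains a 4-fold interaction increase (recorded for scoring the
differential caller). MeDIP tracks have baseline 1 with a multiplicative
Gaussian dip at each TSS (depth 0.6, σ = 1 kb) and rise at each TES
(amplitude 0.8, σ = 2 kb); 20 hyper and 10 hypo 5-kb DMRs at fold 4 are
planted on the 1-kb window grid (treated condition only), at 2×10⁶ expected
counts per replicate. Peaks come in three placement classes — boundary
(truncated-Gaussian jitter, sd 20 kb, clipped to ±1 bin at 40 kb), promoter
(±1 kb of a TSS) and random — with widths of 200–500 bp.

What the generator does not emulate: restriction-fragment geometry, trans
contacts, copy-number structure, read-level errors, CpG-density-dependent
MeDIP efficiency, overlapping/nested genes at realistic density, and
chromosome-scale heterogeneity of decay. Recovery results on this data
therefore demonstrate the pipeline's correctness under its own model
assumptions, not performance on real libraries.

## Numerical choices and degenerate inputs

Seeds: every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from the master seed arithmetically, and identical seeds
give byte-identical outputs (reports carry no timestamps; timers go to the
log). Tolerances: ICE tol 1e-5 on row-sum CV (1e-9 where bias recovery
itself is measured); HMM EM tol 1e-4; p-value pmf comparisons use a 1+1e-7
relative guard, matching the reference implementation. Ties: gene-density
orientation uses a stable sort; nearest-TSS ties go to the smaller
coordinate; PC1 = 0 and TAD score = 0 are masked, not labeled. Degenerate
inputs: all-bins-masked matrices, empty peak sets, empty DMR sets, empty
state paths and sub-3-bin domains all return empty results or are skipped
with log entries rather than raising mid-pipeline; genuinely contradictory
inputs (mismatched bin tables, trans records, misaligned truth intervals,
unknown config keys) raise named errors before compute.

## Known limitations

The compartment caller needs ≥ 10 usable bins per chromosome and assumes
one dominant checkerboard; sub-compartments and saddle metrics are out of
scope. The DI/HMM caller is non-hierarchical and tends to split domains at
strong compartment transitions (which real callers also do). The pooled
binomial differential test ignores biological dispersion — with two
replicates this is explicit policy, and the replicate-concordance
diagnostic is the guard. Boundary regions from clean segmentations are
often 1 bp wide, making raw boundary-overlap fractions conservative;
enrichment profiles around boundary midpoints are the robust alternative
and are reported alongside.
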