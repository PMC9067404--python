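# Methods

This note documents the models, defaults, and design choices behind
tilescan, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and conventions

CDS nucleotides are 1-based; amino acids are 1-based inclusive intervals
(`cut_aa = floor((cut_nt−1)/3)+1`); BED export is 0-based half-open in
amino-acid units. Cas9 is assumed to cut bluntly 3 bp 5′ of the NGG PAM,
i.e. between protospacer bases 17 and 18; `cut_nt` records the
coding-strand base immediately 5′ of the cut. Nontargeting controls
(NTCs) live in the same guide table under the reserved gene name `NTC`
with no cut coordinates, which keeps joint Z-scoring trivial.

## Guide enumeration and quality flags

`enumerate_guides` reports every 20-mer followed by NGG on either strand
whose cut site falls inside the CDS, deduplicated on protospacer
(ambiguously mapping protospacers are dropped entirely). Guides whose
23-mer spans the stop codon are kept as long as the cut site is inside
the CDS. Uniqueness screening is exact-match only against the supplied
CDS collection — genome-wide off-target scoring is out of scope and
would require a genome index.

Two sequence flags follow screen practice: `flag_tttt` marks a TTTT run
anywhere in the protospacer (Pol III termination risk; these guides are
excluded from all analyses by default), and `flag_yrich` marks
pyrimidine-rich 3′ ends, by default ≥3 of the final 4 protospacer bases
C/T. The precise Y-rich motif reported in the literature is uncertain,
and this default flags ~31% of random 20-mers; excluding them widens the
effective cut-site spacing from ~14 to ~20 nt. The pipeline therefore
drops only TTTT guides by default and leaves the Y-rich exclusion opt-in
(`drop={"tttt", "yrich"}`), with both window and threshold configurable.

## Dropout scoring

Per replicate, `logfc = log2(((final+c)/F) / ((initial+c)/I))` with raw
column totals F, I and pseudocount c = 0.5. Medians across replicates are
standardized per cell line as `z = (median_logfc − μ)/σ` using moment
estimators over a baseline population: the whole scored library by
default, or NTC-only (in which case the NTC z population has mean 0 and
SD 1 by construction). `mean_z` averages z across cell lines. Because
totals normalize library size, z is invariant to rescaling any sample's
counts (up to the pseudocount, i.e. to ~1e−3 at screen-typical depths).

Gene-level essentiality uses the per-line fraction of guides with
z < −1: a gene is essential when that fraction exceeds 0.09 in at least
one cell line (cutoff, fraction, and number of lines are parameters).

## The deconvolution objective

For one gene, y is the vector of guide `mean_z` ordered by cut site. The
estimator minimizes

    0.5‖y − x‖² + λ₀ Σ f(xᵢ, a₀) + λ₁ Σ f(xᵢ − xᵢ₋₁, a₁),
    f(t, a) = (1 − e^(−a|t|))/a.

Choice of f: it is concave in |t| (so large essential blocks and large
steps are not taxed linearly), reduces to |t| as a → 0, and has second
derivative bounded below by −a. Since the squared spectral norm of the
first-difference operator is < 4, the Hessian of the full objective is
bounded below by (1 − a₀λ₀ − 4a₁λ₁)·I, which reproduces the convexity
gate `1 − a₀λ₀ − 4a₁λ₁ ≥ 0` exactly; the gate is checked before fitting
and violating configurations are rejected. Other transforms can be
plugged in behind the same interface.

The fusion penalty is index-based: unequal cut-site spacing does not
reweight neighboring differences. Guides are few per segment, spacing is
narrow (median 14 nt), and a distance-weighted variant adds a parameter
without observed benefit on the synthetic screens.

## Solver

The transformed problem is solved by majorize–minimize: f is linearized
at the current iterate (tangent weights `e^(−a|t|)`), and each weighted
fused-lasso subproblem

    0.5‖y − x‖² + Σ uᵢ|xᵢ| + Σ wᵢ|xᵢ₊₁ − xᵢ|

is solved *exactly* by an O(n) dynamic program over clipped
piecewise-linear derivatives (taut-string style, extended with node
penalties; numba-accelerated with a pure-Python fallback). Because
subproblems are exact, the objective trace is non-increasing, and under
the convexity gate MM converges to the global minimum. Defaults:
`tol = 1e−8` relative objective change, `max_iter = 100`; the a → 0
fused-lasso solution is the starting point. Fused values are grouped
into segments with absolute tolerance 1e−9.

Numerical cross-checks in the test suite: the plain fused lasso against
its Fenchel dual (a box-constrained least-squares solved by BVLS) to
1e−6, and the transformed objective against dense L-BFGS-B minimization
of an ε-smoothed surrogate (ε-continuation to 1e−9, two starts) to 1e−5.

## Defaults and how they were set

- `lambda1 = 1.0` — the saturated cost of opening a segment (~2λ₁) must
  stay below the quadratic gain of the smallest motif a 14-nt-spaced
  library resolves (≈4 guides stepping ~1 z), while remaining well above
  the per-guide noise scale so pure noise stays a single segment.
- `a1 = 0.23` — most of the convexity budget is spent on fusion
  saturation. That is the point of the transform: a genuinely inactive
  guide inside a depleted block is cheap to isolate instead of being
  averaged into the block, which is what makes region calls robust to
  score replacement.
- `lambda0 = 0.05`, `a0 = 0.5` — a mild pull toward 0 (= neutral
  proliferation) suppresses weak noise plateaus without visibly
  shrinking real depletion. Gate margin at the defaults: 0.055.
- `tau = 1.0`, `min_len_aa = 1` — regions are runs of fitted values
  below the global mean of all genes' fits minus τ NTC-noise SDs. The
  SD unit is the standard deviation of NTC `mean_z` when NTCs are
  present (1.0 otherwise); the margin is deliberately expressed in
  NTC-noise units because the library-wide SD is inflated by true
  signal. Region bounds are the outermost qualifying guides' `cut_aa` —
  conservative; the true boundary may extend to the next guide.

These values were calibrated once on the default synthetic screen and
then frozen. A BIC-type selector (`lambda_select`, score
`n·log(RSS/n) + log(n)·(#segments + #nonzero segments)`, ties toward
larger λ₁) is provided for data-driven selection over a
convexity-respecting grid, but it is not the pipeline default: on
screen-like signals it prefers fits smooth enough to merge away 30-aa
regions, which is the wrong trade for motif discovery.

## Synthetic screens

`simulate_screen` emulates the screen design the package targets: 40
genes of 300–1000 aa tiled at ~14-nt spacing (±2 nt jitter), NTCs scaled
at 601 per 6500 targeting guides, four cell lines × three replicates at
650× coverage. Expected log2 dropout per guide follows the diploid
editing mixture

    μ = s · [ (1−p)² · 1(frameshift-lethal) + (1−(1−p)²) · 1(in region) ],

with s = −3, p = 0.2 by default, so in a frameshift-lethal gene *all*
active guides drop (biallelic-frameshift term) and in-region guides drop
more — the premise of tiling mutagenesis. 10% of guides are inactive
(μ = 0), emulating non-editing sgRNAs. Two non-overlapping regions of
30–80 aa are planted per lethal gene (one per protein half). Counts are
Gamma-Poisson: a shared negative-binomial cell pool per replicate
(dispersion 0.15), lognormal per-sample depth factors (sd 0.2), lognormal
guide-level growth noise (sd 1.0 in log2 units per replicate), Poisson
sequencing at both timepoints.

What the generator does **not** emulate: sequence-dependent editing
efficiency and repair outcomes (inactivity and flags are independent of
true activity, whereas in real data Y-rich/TTTT guides are
inactive-enriched), copy-number effects, guide cross-reactivity,
multi-transcript coordinate ambiguity, and correlated replicate
artifacts. Passing benchmarks therefore demonstrate correct recovery
under the stated noise model, not performance on any particular real
screen.

The NTC-substitution robustness experiment replaces a per-gene fraction
of targeting `mean_z` values with uniform draws from the NTC min–max
range (resampling from empirical NTC values is available), refits, and
scores called regions against the *unperturbed* baseline regions by
region-wise precision/recall with ≥1-aa overlap. The calling threshold
is frozen at its baseline value: the experiment measures degradation of
a fixed standard; letting the global average drift with the injected
NTC values makes recall non-monotone in the replacement fraction. With
no called regions, precision is vacuous and reported as 1.0 with a flag
(likewise recall with no true regions).

## Degenerate inputs and edge cases

Length-1 profiles reduce to soft thresholding; zero penalties return
y; NaNs, negative counts, σ = 0 baselines, empty bins, empty grids,
regions beyond the protein, and conservation tracks shorter than a
region all raise with specific messages. `max_iter` exhaustion returns
the last iterate flagged `converged=False`. Mann–Whitney comparisons
use scipy's two-sided test, which handles single-element bins by the
exact method.

## Known limitations

- Region boundaries are guide-resolution (≈ spacing/3 aa) and
  conservative by construction.
- The per-gene fits share one configuration; genes with atypical guide
  density or depth may prefer different λ (use `lambda_select` on a
  per-screen basis).
- Conservation calls treat the averaged phyloP score on the −log10 P
  scale (conserved iff mean ≥ 1.301 at α = 0.05); averaging per-nt
  P-values before thresholding is a defensible alternative reading and
  would be stricter.
- Exact-match uniqueness screening cannot see off-CDS or mismatch
  off-targets.
- Problem sizes in tests and the acceptance script (40-gene screens,
  ≤5 perturbation seeds per fraction, n ≤ 30 oracle instances) are the
  package's reference benchmark sizes; all scale linearly if enlarged.
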