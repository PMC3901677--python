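# Methods

## The model

`rgcdipoles` simulates mosaics of ON- and OFF-centre retinal ganglion cells
(RGCs) as a bivariate pairwise interacting point process (PIPP) and asks a
single scientific question of them: do the *dipole angles* — the preferred
orientations implied by nearby ON/OFF pairs — carry spatial correlations of
the kind a cortical orientation preference map (OPM) would require?

A configuration of ON positions x₁…x_N and OFF positions y₁…y_M carries a
weight proportional to the product of pairwise interaction values:

- **within a polarity** — soft parametric repulsion
  h(t) = 0 for t ≤ δ, otherwise 1 − exp(−((t − δ)/φ)^α), with hard
  exclusion radius δ (µm), range φ (µm) and shape α. This produces the
  semiregular, exclusion-zone mosaics characteristic of beta cells.
- **between polarities** — a hard step: pairs closer than the soma diameter
  are forbidden, all others are unconstrained (value 1; the boundary is
  inclusive, "not less than" one soma apart).

The **modulated process (mPIPP)** multiplies the ON–OFF step, for pairs
closer than the dipole distance d, by a von-Mises alignment kernel

    m(Δ) = exp(β (cos 2Δ − 1)),

where Δ = θ − ϑ(midpoint) is the difference between the pair's dipole
orientation θ (orthogonal to the ON→OFF vector, mod π) and the OPM
orientation at the pair midpoint. The kernel is π-periodic, equals 1 at
perfect alignment and exp(−2β) at orthogonality, and reduces the process to
the plain PIPP exactly at β = 0. When a candidate position lies within d of
several opposite-polarity cells, one kernel factor per such cell enters the
product (the flexible multi-dipole convention).

Under this kernel the angular density of a dipole is ∝ exp(β cos 2Δ), so
the expected OPM/dipole cross-correlation ⟨cos 2Δ⟩ is the Bessel ratio
I₁(β)/I₀(β) — the analytic curve the simulations are validated against
(`analytic_cross_correlation`, checked independently by quadrature in the
test suite).

## Monte-Carlo procedure

Cells start uniformly at random (a binomial point pattern at fixed counts).
Each sweep visits all ON cells and then all OFF cells; for each cell one
uniform candidate position is proposed and accepted with probability equal
to the product of its interaction values against all other cells, keeping
the old position otherwise. Every accepted move is therefore an exact draw
from the cell's conditional density, so the sweep scheme is a
rejection-sampling Gibbs sampler for the product measure. Runs are
bit-reproducible given the seed (PCG64).

Mixing: at the default parameters acceptance is ≈ 0.3 per proposal and the
default 20 sweeps equilibrate the patterns and their dipole statistics.
Strong modulation (β ≳ 10) lowers acceptance and slows mixing; equilibrium
properties (the Bessel-ratio cross-correlation, the OPM-tracking
correlation structure) are therefore measured from long runs of 120–150
sweeps, a burn-in choice, while workflow defaults remain at 20 sweeps.
Acceptance rates per polarity are logged on the simulation state so users
can raise `n_sweeps` when needed.

Feasibility is checked before simulating: the requested counts must not
exceed the densest hard-disc packing for their exclusion radii.

## Reference study conditions (presets)

The package's defaults define a cat-beta-cell-like reference condition used
by the power analysis and the acceptance checks:

| parameter | value | why |
|---|---|---|
| window | 1 mm² (1000×1000 µm) | linear extent of the published cat fields |
| densities | 72 ON + 76 OFF per mm² | chosen analytically so the unmodulated process yields the reported mean of ≈ 98.6 dipoles at d = 80 µm (set-covariance edge term and soma hard core included); consistent with mid-peripheral beta-cell densities |
| δ, φ, α | 30, 40 µm, 2.5 (both polarities) | semiregular mosaics (nearest-neighbour CV ≈ 0.26) whose Monte-Carlo acceptance (≈ 0.3) equilibrates within tens of sweeps |
| soma diameter | 15 µm | beta-cell soma scale; the only heterotypic constraint |
| dipole distance d | 80 µm | middle of the sensible 60–100 µm range set by the ON/OFF nearest-neighbour distribution |
| column spacing Λ | 1.0 mm cortex | typical cat orientation-column spacing |
| magnification M | 1.7 mm cortex / mm retina | pairs ~1 mm retinal fields with ~1.7 mm cortical regions; Λ_retina = Λ/M ≈ 588 µm |

## Synthetic orientation-preference fields

Measured OPMs are emulated by bandpass-filtered complex Gaussian noise:
white noise is multiplied in Fourier space by a Fermi bandpass
F(k) = σ(k_low − k) · σ(k − k_high) (σ the logistic with steepness k₀/10;
band edges k₀(1 ± rel_bandwidth) around k₀ = 2π/Λ; the k = 0 component
removed), and ϑ = arg(z)/2 mapped into [0, π). The result has a single
dominant column spacing Λ, a uniform orientation marginal, and the
characteristic autocorrelation of such fields: positive locally, first zero
near 0.38Λ, negative around Λ/2, decaying beyond. What the generator does
*not* emulate: pinwheel-density statistics of real maps, anisotropy,
inhomogeneous signal strength, or measurement noise — so tests passing on
synthetic fields show the machinery behaves as designed, not that real
imaging data would behave identically. Fields are sampled at arbitrary
positions by nearest-pixel lookup (pixel size 10 µm ≪ Λ makes interpolation
immaterial); positions outside the footprint clip to the nearest in-bounds
pixel, and the simulator refuses OPMs that do not cover the window.

## Dipoles and correlation functions

An ON/OFF pair with separation strictly smaller than d is a dipole; its
orientation is the direction of the ON→OFF vector rotated by π/2, reduced
mod π, and its position is the midpoint. One cell may appear in many
dipoles. All circular statistics use the plain π-periodic correlation
⟨cos 2Δθ⟩ — for dipole pairs binned by midpoint separation
(`dipole_correlation`, unordered pairs, i ≠ j), for OPM pixel pairs
(`opm_autocorrelation`), and for the dipole-to-OPM alignment
(`cross_correlation`). Bins without pairs are undefined (NaN), never zero.
Confidence intervals come from resampling dipoles with replacement
(percentile bootstrap, ≥ 100 resamples). The default binning divides the
window diagonal into 20 equal bins. Note that under the uniform null the
pair statistic is a degenerate U-statistic: its sampling error shrinks
roughly like 1/n_dipoles, faster than the 1/√n intuition.

## Classical mosaic statistics

- **G-function**: raw empirical distribution of nearest-neighbour
  distances (no edge correction).
- **L-function**: L = √(K/π) with the translation-edge-corrected K
  estimator (switchable to "none" for oracle comparisons); values beyond a
  quarter of the shorter window side are truncated to NaN with a warning.
- **Autocorrelogram**: all pairwise displacement vectors within a radius,
  inversion-symmetric by construction. Isotropy checks should stay at lags
  well below the window size, where the window's set covariance is flat.
- **Voronoi disorder μ₂**: variance of the side-count distribution of
  Voronoi cells, after discarding unbounded cells and cells with vertices
  outside the window; near-duplicate vertices are merged before counting.
  μ₂ = 0 for a perfect hexagonal lattice, ≈ 1.78 for Poisson patterns.
- **Envelopes**: pointwise 2.5–97.5 percentile bands over ≥ 99 seeded
  simulations (percentiles, not min/max, for stability at 99).

## Hypothesis tests

All p-values are rank-based Monte-Carlo probabilities. With an ensemble of
m statistic values T and an observed value S,

    p = (1 + #{T at least as extreme as S}) / (m + 1),

ties counted as extreme, so p lives on {1/(m+1), …, 1}, is uniform on that
lattice under the null, and equals exactly 0.01 when S is more extreme
than all of m = 99 ensemble values. T and S are band-summed deviations of
a correlation function from the ensemble mean, Σ_band (C(r_k) − C̄(r_k)).
Bands: the *local* band (bin centers ≤ 100 µm, where modulation produces
positive correlation), the *anticorrelation* band (200–400 µm), and a
threshold band (bins with C̄ > 0.1) for scans against modulated ensembles.

- **Goodness of fit of local statistics** (`local_stats_pvalue`): the
  observed mosaic and m ≥ 99 simulations are each scored by their
  integrated squared deviation from the leave-one-out mean of the others
  (G or L curves) or squared deviation of the scalar μ₂; upper-tail rank
  p-value; p ≤ 0.05 flags misfit.
- **(β, M) consistency scan** (`beta_magnification_scan`): per grid cell,
  n_real mPIPP realizations — each modulated by an independently sampled
  OPM region whose retinal footprint follows the magnification — give the
  T distribution; S comes from the observed correlation function below a
  distance cutoff. Two-sided by default so the scan flags data that is
  either less or more correlated than the cell's ensemble (floor 2/(m+1)).
- **Statistical power / false-negative rate**
  (`estimate_false_negative_rate`): an unmodulated PIPP pool (n_pipp
  realizations at the reference densities scaled to the requested area) is
  built once. Each of n_repeats repeats resamples 100 correlation
  functions from the pool, forms T from n_draws averages of N resampled
  functions, computes S from N fresh mPIPP realizations at β, and records
  the one-sided rank p (upper tail for the local band, lower for the
  anticorrelation band). The false-negative rate is the fraction of
  repeats with p > α = 0.05; at β = 0 it calibrates to ≈ 1 − α.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale:
99-realization ensembles for envelopes and the dipole-yield check, 12 long
runs per β for the Bessel-ratio check, and the power procedure at
n_pipp = 200, n_repeats = 200 (the full-fidelity settings of 500/1000 are
plain function arguments). These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Numerical choices and degenerate inputs

- Coordinates are retinal µm everywhere; cortical lengths enter only via
  M (linear retinotopy).
- Boundary conventions: intra-repulsion is 0 at t = δ (continuous from
  above); the heterotypic step is 1 at exactly one soma diameter; dipole
  extraction uses strict inequality (separation < d).
- Collinear point files get a minimally opened bounding-box window.
- Coincident ON/OFF points have no orientation and are a validation error.
- No boundary correction is applied to dipole extraction; edge dipoles are
  mildly depleted, which matters little at the small β values the data
  support.
- Mosaic text files are written at 6 significant digits and round-trip
  bit-identically after one write→read cycle.

## Known limitations

- **Kernel normalization.** The alignment kernel is normalized to maximum 1
  so that acceptance stays a probability. Its angular mean is therefore
  < 1, which thins ON/OFF pairs inside d as β grows — dipole yields drop
  faster with β than a mean-preserving modulation would produce, and at
  β = 30 the effective heterotypic repulsion induces mild same-type
  clustering (the L-function rises by ~10 µm at 50–140 µm lags relative to
  β = 0, while μ₂ is unaffected). The 95% envelopes of G, L and μ₂ still
  overlap pointwise across β ∈ {0, 2.5, 30}. At the small β values that
  matter for comparisons with data (β ≲ 2.5) the effect is minor.
- The dipole angle is the entire model of orientation preference: no
  receptive-field subfields, no tuning curves, no LGN transformation.
- Power estimates use synthetic OPM regions; with measured maps the
  quantitative false-negative rates could shift, though the calibration at
  β = 0 would not.
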