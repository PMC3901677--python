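# rgcdipoles

Spatial statistics of ON/OFF retinal ganglion cell (RGC) mosaics and the
orientations of their *dipoles* — nearby ON/OFF pairs whose implied
preferred orientation is orthogonal to the vector joining the two cells.

Under the statistical connectivity picture of primary visual cortex, a V1
neuron dominated by one ON/OFF dipole inherits that dipole's orientation,
so a smooth, roughly periodic cortical orientation preference map (OPM)
requires dipole angles that are locally correlated and anti-correlated at
intermediate distances. This package provides the machinery to state and
test that requirement quantitatively:

- a **pairwise interacting point process (PIPP)** for ON/OFF mosaics —
  soft homotypic repulsion h(t) = 1 − exp(−((t − δ)/φ)^α) beyond a hard
  core, plus a hard heterotypic step at the soma diameter — and its
  **OPM-modulated variant (mPIPP)**, which multiplies the ON–OFF
  interaction of pairs closer than the dipole distance d by
  exp(β(cos 2Δ − 1)), Δ being the angle between the dipole orientation and
  the OPM at the pair midpoint. β = 0 is exactly the plain PIPP; the
  expected OPM/dipole alignment is the Bessel ratio I₁(β)/I₀(β).
- **synthetic OPMs**: Fermi-bandpass-filtered complex Gaussian noise with
  a single dominant column spacing Λ and uniform orientation histogram,
  mapped to retinal coordinates through a linear cortical magnification M.
- **dipole analysis**: extraction at a distance d, π-periodic circular
  correlation functions C(r) = ⟨cos 2(θᵢ − θⱼ)⟩ with bootstrap CIs, and
  OPM cross-correlation.
- **classical mosaic statistics**: G- and (translation-edge-corrected)
  L-functions, autocorrelograms, Voronoi topological disorder μ₂, and
  95% simulation envelopes.
- **Monte-Carlo inference**: rank p-values (floor 0.01 at 99 simulations),
  goodness-of-fit tests for local statistics, a (β, magnification)
  consistency scan, and a simulation-based false-negative-rate (power)
  analysis for detecting dipole-angle correlations in data sets of a given
  number and size of mosaics.

A noisy-hexagonal Moiré generator is included as the classical contrast
model: its dipole pattern keeps periodic correlations at long range,
whereas mPIPP mosaics decorrelate beyond 2–3 Λ.

## Worked example

Simulate a weakly modulated mosaic at the package's cat-beta-cell-like
reference conditions (1 mm², 72 ON + 76 OFF cells, d = 80 µm, Λ ≈ 588 µm
retinal), extract its dipoles and measure their correlations:

```python
from rgcdipoles import (simulate_mpipp, extract_dipoles, dipole_correlation,
                        cross_correlation, analytic_cross_correlation)
from rgcdipoles.inference import synthetic_opm_sampler
from rgcdipoles.presets import (CAT_BETA_INTERACTIONS, CAT_MAGNIFICATION,
                                DIPOLE_DISTANCE, M623_WINDOW, default_config,
                                mosaic_counts)

opm = synthetic_opm_sampler()(42, M623_WINDOW, CAT_MAGNIFICATION)
mosaic = simulate_mpipp(M623_WINDOW, *mosaic_counts(1.0), CAT_BETA_INTERACTIONS,
                        opm=opm, cfg=default_config(beta=2.5, seed=1, n_sweeps=120))
dipoles = extract_dipoles(mosaic, DIPOLE_DISTANCE)
corr = dipole_correlation(dipoles, 20, mosaic.diagonal)
print(len(dipoles), cross_correlation(dipoles, opm), analytic_cross_correlation(2.5))
```

This run prints 52 dipoles with an OPM/dipole cross-correlation of 0.783
against the analytic expectation 0.765, and a correlation function whose
first bins decay from local alignment to zero:

```
    35.4 um  C = +0.682  (16 pairs)
   106.1 um  C = +0.449  (57 pairs)
   176.8 um  C = +0.236  (73 pairs)
   247.5 um  C = +0.181  (103 pairs)
   318.2 um  C = +0.001  (98 pairs)
```

The same β = 2.5 process yields markedly fewer dipoles than the β = 0
process (the modulation thins misaligned pairs), and the unmodulated PIPP
at these densities averages ≈ 98.5 dipoles per realization.

A command-line interface mirrors the library
(`rgcdipoles synth-opm | simulate | dipoles | correlate | stats | moire |
scan | power | pipeline`); every stochastic command takes `--seed` and
writes a JSON run manifest, and `rgcdipoles pipeline --config cfg.yaml
--out outdir` runs the synth-OPM → simulate → dipoles → correlate workflow
end to end, byte-reproducibly for a fixed seed.

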