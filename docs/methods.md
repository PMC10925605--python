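# Methods

This note documents the models and procedures implemented in
`eigenmarkers`, the parameters that matter, the synthetic data the test
suite runs on, and the design decisions taken where the methodology was
genuinely open.

## Temporal preprocessing

Parcellated runs (timepoints × regions, TR in seconds) are cleaned in two
steps, both shape- and metadata-preserving.

**Band-pass + notch filtering** is realised as brick-wall masking of the
real FFT of each region's series: bins below `low_cut`, above
`high_cut`, and the bin nearest the notch frequency (± one bin by
default, configurable) are zeroed, and the series inverse-transformed.
Amplitude-only masking is exactly zero-phase and idempotent, which the
suite asserts to 1e-10.  Defaults: pass band 0.0025–0.05 Hz, notch
0.03 Hz — the slow-fluctuation band and narrowband-artefact frequency
typical of anaesthetised-macaque resting-state acquisitions (TR 1.25 s or
2.4 s, 500 volumes).  If the record is shorter than one cycle of
`low_cut` the corner is unresolvable; the filter warns and removes only
the DC bin.  Filtering a 500-sample run to this band leaves ~30 of 251
rFFT bins, so downstream FC matrices are rank-deficient; this is expected
and handled (see hierarchy notes).

**Global-signal regression** removes, per region, the OLS projection onto
the per-timepoint mean across regions plus an intercept.  It is off by
default and enabled per dataset (`PipelineConfig.global_signal_regression`),
because contrast-agent acquisitions commonly apply it while BOLD
protocols may not; the default pipeline order is filter → GSR.

## Harmonic mode decomposition

The connectome is symmetrised by averaging mirror entries, the diagonal
zeroed, and connectivity verified (a disconnected graph is a hard error
naming the smallest component).  The symmetric normalised Laplacian
`D^{-1/2}(D − C)D^{-1/2}` has unit diagonal and spectrum in [0, 2]; its
full eigendecomposition gives exactly N modes.  For a connected graph the
smallest eigenvalue is exactly zero with the uniform-sign mode
`φ_1 ∝ D^{1/2}1`; that mode is included as mode 1 and carries zero
energy by construction, which is what makes globally coherent activity
"free" in energy terms.

Projection is exact (`ω(t) = Φᵀ F_t`), so Parseval holds per timepoint
and the expansion reconstructs the data; both are asserted at 1e-10.
Timepoints enter as-is after preprocessing — no per-timepoint
normalisation — so energy scales with signal variance.  The scan-level
summary is the sum of mode energies per timepoint, averaged over time;
per-mode time-averaged energies are also exposed for spectral profiles.

Numerical conventions: every eigenvector is flipped so its
largest-magnitude entry is positive (ties → lowest region index), making
outputs reproducible; within a degenerate eigenvalue the eigenvectors are
one valid orthonormal choice and only aggregate quantities are
convention-free, so tests use non-degenerate fixtures and a warning is
emitted when consecutive eigenvalues tie within 1e-10.

## Functional gradients

Pearson FC → Fisher z (diagonal excluded and set to 0; |r| clipped at
1 − 1e-7 so atanh stays finite) → per-row retention of the
`k = round(density·(N−1))` largest *signed* z-values (ties toward the
lower column index; N = 82 at 10 % density keeps 8 per row) → similarity
between thresholded rows.  Thresholding is asymmetric; the row-kernel
restores symmetry.  `normalized_angle` (default) maps the profile angle
to [0, 1]; plain `cosine` is clipped at 0 to keep the affinity
non-negative.

The embedding α-normalises the affinity (`W' = D^{-α} W D^{-α}`,
α = 0.5 by default, balancing local and global geometry), row-normalises
to a Markov matrix, and diagonalises through the symmetric conjugate.
Right eigenvectors are scaled so the trivial eigenvalue-1 mode is the
constant vector and then dropped; component k is scaled by
`λ_k/(1 − λ_k)` at the default `diffusion_time = 0` (multi-scale
convention) or `λ_k^t` otherwise.  A disconnected affinity (eigenvalue 1
with multiplicity > 1) is an error.  Ten components are retained by
default; the markers use components 1–3.

Markers — range of a component, dispersion
`Σ_i ‖x_i − centroid‖²` over the first three components (equal to
N · trace of the biased coordinate covariance), and eigenvalue ratio
`λ_1/Σλ` over the retained components — are invariant to component sign,
region relabelling, and (for dispersion) rotation of the 3-space, so no
cross-scan gradient alignment is performed and none is needed.  Whether
the eigenvalue ratio should use all N−1 eigenvalues or the retained m is
not canonical; the retained m is the default and `n_components` makes it
configurable.

## Hierarchical integration and segregation

FC eigenvalues are sorted descending (FC is PSD up to round-off; tiny
negative values are clamped to 0 before squaring).  The nested sign
partition starts from one whole-cortex module; at level i every existing
module splits into its non-negative and negative subsets under
eigenvector i, exact zeros grouping with +, empty subsets dropped.
Levels run to i = N; once all modules are singletons the remaining terms
accumulate with `M_i = N`, `p_i = 0`, per the literal sum.  Because
band-pass filtering makes empirical FC rank-deficient, trailing
eigenvalues tie at zero and the corresponding partitions are
solver-dependent — the code warns, and those levels contribute nothing to
H_Se since their eigenvalues vanish.  Closed-form anchors used in the
tests: for 2 regions at correlation r, `H_In = (1+r)²/4` and
`H_Se = (1−r)²/2`; a 4-region Hadamard-eigenvector fixture gives
`H_Se = 0.203125` by hand.

## Behavioural arousal scale

Six observer-rated criteria — exploration 0–2, spontaneous movements
0–2, shaking/prodding 0–2, toe-pinch response 0–2, eye opening 0–2,
corneal reflex 0–1 — sum to a 0–11 composite.  Condition scores are
deterministic (no within-condition variability is modelled): awake 11;
ketamine, deep propofol/sevoflurane, stimulation-off, and ventro-lateral
stimulation 0; light sevoflurane 3; light propofol 4; centro-median
stimulation 3 (low amplitude) or 9 (high).  The generic
`light_anaesthesia` preset uses 3.  The map ships as a JSON resource;
sub-score validation names the offending criterion.

## Dominance analysis and statistics

Markers are min–max scaled within each dataset before pooling (shift by
the group minimum, divide by the post-shift maximum, so each dataset
spans [0, 1] exactly).  Dominance analysis fits OLS on every non-empty
predictor subset; total dominance of predictor j averages its incremental
fit first within each subset size and then across sizes.  With unadjusted
R² (the default) the dominances sum to the full-model R² exactly — the
suite asserts 1e-8 — and relative importances sum to 100 %; an
adjusted-R² mode is provided for reporting conventions that average
adjusted increments, at the cost of exact additivity.  The classification
variant dichotomises arousal at 9 (wakefulness + high centro-median
stimulation vs rest) or 3 (any arousal vs none) and uses unpenalised
logistic submodels scored by McFadden pseudo-R²; when conditions are
perfectly separable every subset saturates the fit and importances
flatten, which is visible on clean synthetic data.

The permutation test reshuffles the response and reports
`p = (1 + #{null ≥ observed})/(1 + n_perm)` (never exactly zero; 1000
permutations by default, seeded).  Under the null the p-value is uniform,
asserted by a KS test over 200 repeats.  FDR adjustment is
Benjamini–Hochberg step-up (delegated to statsmodels and cross-checked
against a hand-coded oracle); the correction family is the caller's
choice, with per-marker-across-conditions the intended default.  Mixed
-effects modelling of condition contrasts is deliberately out of scope:
the marker table is written tidy so any standard LME routine can consume
it.

## Synthetic data: what it emulates and what it does not

A run is generated by inverting the harmonic expansion:
`F_t = Σ_k ω_k(t) φ_k + ε_t`, `ω_k(t) ~ N(0, σ_k²)` i.i.d. over time,
`ε` isotropic with `noise_sd = 0.3`.  The connectome generator builds a
4-module weighted graph (82 regions by default; within/between edge
probabilities 0.9/0.3, lognormal weights around strengths 1.0/0.1 with
sigma 0.2), bridging any disconnected draw with a warning.  Condition
presets (versioned JSON resource) set the spectral profile σ_k:

* `integration_sd` — σ of the λ = 0 global mode: whole-cortex coherence,
  high H_In, zero energy;
* `gradient_sd` — σ of modes 2–3, the smooth modular axes: bimodular FC
  and a wide principal gradient;
* `tail_sd`, `tail_decay` — exponential profile over the remaining
  modes: a slow decay pushes variance into high-λ modes and raises
  harmonic energy.

Awake-like presets (awake, high-amplitude centro-median stimulation) have
strong global/gradient loadings and a fast-decaying tail; the
deep-anaesthesia-like presets (deep anaesthesia, stimulation-off,
ventro-lateral stimulation) the opposite; light anaesthesia and
low-amplitude stimulation sit between.  The constants were calibrated
once so the qualitative condition contrasts hold robustly (awake > deep
on gradient range and H_In, awake < deep on scan energy, in ≥ 95 % of
seed pairs — empirically 100 % in the shipped configuration).

What the generator does **not** emulate: haemodynamic convolution and
temporal autocorrelation, contrast-agent versus BOLD differences,
inter-animal variability, motion or physiological artefacts, and any
genuine cortical gradient topography.  Passing tests therefore
demonstrate that the pipeline measures what it claims on data with the
assumed statistical structure — not that real recordings have that
structure.

## Problem sizes and determinism

Default study sizes mirror a realistic protocol at desk scale: 82
regions, 500 timepoints per run, 4 runs per condition, 3 + 6 conditions
across two datasets (36 runs end-to-end).  The marker-direction suite
uses 50 independent connectome/run seed pairs at full 82-region size; the
permutation-calibration suite 200 repeats of a 199-permutation test; the
spectrum-recovery check 10 000 timepoints at 30 regions.  All randomness
flows through seeded `numpy` generators; dataset writes are byte-stable
under a fixed seed, and every pipeline output embeds a hash of the
resolved configuration.
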