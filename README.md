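# eigenmarkers

Eigenmode-based distributed markers of cortical arousal for parcellated
primate fMRI.

Loss of consciousness under anaesthesia is not a local event: it reshapes
how activity is organised across the entire cortex, and targeted thalamic
deep-brain stimulation can partially reverse it.  `eigenmarkers`
implements three complementary whole-cortex signatures of that
reorganisation, each derived from an eigendecomposition, plus the
statistics to relate them to a behavioural arousal score:

1. **Harmonic energy** (structure–function coupling).  The structural
   connectome `C` defines the symmetric normalised graph Laplacian
   `Δ_G = D^{-1/2}(D − C)D^{-1/2}` with orthonormal harmonic modes
   `Δ_G φ_k = λ_k φ_k`, `0 = λ_1 ≤ … ≤ λ_N`.  Each BOLD timepoint `F_t`
   is expanded as `F_t = Σ_k ω_k(t) φ_k` with `ω_k(t) = ⟨F_t, φ_k⟩`; the
   power of mode `k` is `|ω_k(t)|` and its energy `ω_k(t)² λ_k²`.  Scan
   energy (mean over time of the summed mode energy) is high when
   activity is pinned to fine-grained anatomical structure and zero for
   purely global fluctuations.
2. **Functional gradients.**  Per run, Pearson FC is Fisher-z
   transformed, row-thresholded to 10 % density, converted to a
   normalized-angle similarity matrix and embedded with anisotropic
   diffusion map embedding (α = 0.5).  Markers: range (max − min) of
   gradients 1 and 2, dispersion in the first three gradients, and the
   principal eigenvalue ratio `λ_1 / Σ λ_k`.
3. **Hierarchical integration and segregation.**  From `FC = U Λ Uᵀ`, a
   nested sign partition splits modules recursively by the sign of
   successive eigenvectors.  With module counts `M_i` and size correction
   `p_i = Σ_j |m_j − N/M_i| / N`:
   `H_In = Λ_1²/N²` and `H_Se = Σ_{i≥2} Λ_i² M_i (1 − p_i)/N²`.
4. **Brain–behaviour dominance analysis.**  Markers are min–max
   normalised within each dataset and regressed against the 0–11
   behavioural arousal composite (six observer-rated criteria).  Total
   dominance averages each predictor's incremental R² over all `2^p − 1`
   predictor subsets; significance comes from a permutation test of the
   full-model fit, with a dichotomised (logistic, McFadden pseudo-R²)
   classification variant and Benjamini–Hochberg FDR utilities.

Because raw macaque recordings are not publicly downloadable, the package
ships a first-class synthetic generator (`eigenmarkers.synthetic`) that
builds modular connectomes and condition-dependent mode-mixture BOLD runs
for awake, light/deep anaesthesia, and centro-median / ventro-lateral
thalamic stimulation presets, so the entire pipeline runs end-to-end from
a seed.

## Worked example

```bash
python examples/brain_behaviour.py
```

```
Dominance analysis of arousal on distributed cortical markers
  runs: 36  predictors: 3  submodels fitted: 7
  full-model R^2 = 0.9705 (adjusted 0.9677); permutation p = 0.000999 (1000 permutations, seed 0)
  relative importance:
    gradient_range                36.40 %  (dominance 0.3533)
    hierarchical_integration      32.38 %  (dominance 0.3142)
    harmonic_energy               31.22 %  (dominance 0.3030)
```

Two synthetic datasets (24 + 12 runs, 82 regions, 500 timepoints each)
are generated, the marker table computed, and arousal regressed on the
three normalised markers: all 7 subset models are fitted, each marker
contributes roughly a third of the explained variance, and no score
reshuffle out of 1000 reaches the observed fit (p = 1/1001).  The other
examples (`harmonic_energy.py`, `functional_gradients.py`,
`hierarchical_integration.py`) print the per-marker condition contrasts,
e.g. scan energy 8.5 (awake-like) vs 23.3 (deep-anaesthesia-like) and
principal-gradient range 0.29 vs 0.14 on the same connectome.

A thin CLI mirrors the library:

```bash
eigenmarkers simulate study/ --seed 1
eigenmarkers markers study/ --out markers.csv
eigenmarkers brain-behaviour markers.csv --out dominance.json --arousal-csv study/arousal.csv
```

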