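"""Harmonic energy: how structurally constrained is cortical activity?

Builds a synthetic 82-region modular connectome, extracts its Laplacian
harmonic modes, simulates one awake-like and one deep-anaesthesia-like
BOLD run, and compares their scan-level harmonic energy.  Energy weights
every mode's squared contribution by its squared eigenvalue, so activity
concentrated in fine-grained, high-spatial-frequency modes scores high,
while globally coherent activity (the lambda = 0 uniform mode) scores
zero.
"""

import numpy as np

from eigenmarkers import (
    connectome_basis,
    decompose_timeseries,
    generate_connectome,
    generate_timeseries,
    load_presets,
    scan_energy,
)

sc = generate_connectome(n_regions=82, n_modules=4, seed=42)
basis = connectome_basis(sc)
print(f"connectome: {sc.n_regions} regions -> {basis.n_modes} harmonic modes")
print(f"eigenvalue range: {basis.eigenvalues[0]:.2e} .. {basis.eigenvalues[-1]:.3f}")

presets = load_presets()
for name in ("awake", "deep_anaesthesia"):
    ts = generate_timeseries(basis, presets[name], n_timepoints=500, seed=7)
    spectrum = decompose_timeseries(ts, basis)
    energy = scan_energy(spectrum)
    # where does the energy live along the spatial-frequency axis?
    cum = np.cumsum(spectrum.mode_energy) / spectrum.mode_energy.sum()
    half = int(np.searchsorted(cum, 0.5)) + 1
    print(
        f"{name:18s} scan energy = {energy:7.2f}  "
        f"(half the energy below mode {half})"
    )

print(
    "\nHigher energy under the anaesthesia-like preset means activity is\n"
    "spread into high-spatial-frequency modes of the anatomical network,\n"
    "i.e. more tightly constrained by structure; the awake-like preset\n"
    "concentrates variance in smooth global modes that carry little energy."
)
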