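"""Hierarchical integration and segregation from FC eigenmodes.

First walks through a tiny closed-form case (2 regions, correlation r),
then compares the markers between awake-like and anaesthesia-like
synthetic runs.  H_In is the covariance share of the single whole-cortex
module; H_Se sums the contributions of all partitioning eigenmodes,
weighted by module count and corrected for uneven module sizes.
"""

import numpy as np

from eigenmarkers import (
    compute_fc,
    connectome_basis,
    decompose_hierarchy,
    generate_connectome,
    generate_timeseries,
    load_presets,
)

r = 0.6
decomp = decompose_hierarchy(np.array([[1.0, r], [r, 1.0]]))
print(f"2-region FC with r = {r}:")
print(f"  eigenvalues  = {decomp.eigenvalues.round(4).tolist()}   (1+r, 1-r)")
print(f"  H_In = {decomp.h_in:.4f}   closed form (1+r)^2/4 = {(1 + r) ** 2 / 4}")
print(f"  H_Se = {decomp.h_se:.4f}   closed form (1-r)^2/2 = {(1 - r) ** 2 / 2}")

sc = generate_connectome(n_regions=82, seed=5)
basis = connectome_basis(sc)
presets = load_presets()
print(f"\n{'condition':18s} {'H_In':>9s} {'H_Se':>9s} {'modules at level 4':>20s}")
for name in ("awake", "deep_anaesthesia"):
    ts = generate_timeseries(basis, presets[name], n_timepoints=500, seed=9)
    decomp = decompose_hierarchy(compute_fc(ts))
    print(
        f"{name:18s} {decomp.h_in:9.4f} {decomp.h_se:9.4f} "
        f"{decomp.module_counts[3]:>20d}"
    )

print(
    "\nThe awake-like preset keeps a dominant whole-cortex mode (high\n"
    "H_In); under the anaesthesia-like preset covariance fragments into\n"
    "many fine modules, collapsing integration."
)
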