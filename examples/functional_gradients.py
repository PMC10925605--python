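"""Functional gradients: the geometry of connectivity profiles.

Simulates awake-like and deep-anaesthesia-like runs on the same synthetic
connectome, embeds each run's functional connectivity with diffusion map
embedding, and prints the gradient markers: range of the first and second
gradients, three-gradient dispersion, and the principal eigenvalue ratio.
"""

from eigenmarkers import (
    build_affinity,
    compute_fc,
    connectome_basis,
    diffusion_map_embedding,
    generate_connectome,
    generate_timeseries,
    gradient_dispersion,
    gradient_range,
    load_presets,
    principal_eigenvalue_ratio,
)

sc = generate_connectome(n_regions=82, seed=11)
basis = connectome_basis(sc)
presets = load_presets()

print(f"{'condition':18s} {'range g1':>9s} {'range g2':>9s} "
      f"{'dispersion':>11s} {'ev ratio':>9s}")
for name in ("awake", "light_anaesthesia", "deep_anaesthesia"):
    ts = generate_timeseries(basis, presets[name], n_timepoints=500, seed=3)
    fc = compute_fc(ts)
    affinity = build_affinity(fc, density=0.10, kernel="normalized_angle")
    emb = diffusion_map_embedding(affinity, alpha=0.5, n_components=10)
    print(
        f"{name:18s} {gradient_range(emb, 1):9.4f} {gradient_range(emb, 2):9.4f} "
        f"{gradient_dispersion(emb, 3):11.4f} {principal_eigenvalue_ratio(emb):9.4f}"
    )

print(
    "\nA wide principal gradient means regions occupy a deep axis of\n"
    "differentiated connectivity profiles; under the anaesthesia-like\n"
    "preset the embedding contracts toward the origin on every measure."
)
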