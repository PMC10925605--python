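"""Synthetic connectomes and condition-dependent BOLD time series.

The generator inverts the harmonic decomposition the analysis assumes:
a parcellated BOLD run is built as F_t = sum_k omega_k(t) phi_k + noise
with independent Gaussian mode coefficients omega_k(t) ~ N(0, sigma_k^2)
on the harmonic basis of a modular synthetic connectome.  A condition
preset fixes the per-mode scale profile sigma_k:

* ``integration_sd`` loads the lambda = 0 global mode — it creates
  whole-cortex coherent fluctuation (high hierarchical integration) and
  contributes zero harmonic energy;
* ``gradient_sd`` loads modes 2-3, the smooth modular axes of the
  connectome, giving functional connectivity a strong bimodular
  organisation that widens the principal functional gradient;
* ``tail_sd`` and ``tail_decay`` shape an exponential profile over the
  remaining modes — a slow decay spreads variance into
  high-spatial-frequency modes, raising the eigenvalue-weighted harmonic
  energy, as seen when activity becomes more structurally constrained
  under anaesthesia.

Awake-like presets therefore pair wide gradients and high integration
with low energy; deep-anaesthesia-like presets the reverse.  This is the
minimal statistical structure the markers respond to: no haemodynamics,
no temporal autocorrelation, no inter-animal variability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, RegeneratedGraphWarning
from .harmonics import (
    HarmonicBasis,
    StructuralConnectome,
    build_normalized_laplacian,
    compute_harmonic_basis,
    symmetrize_connectome,
)
from .io import write_connectome_tsv, write_timeseries_tsv
from .preprocessing import ParcellatedTimeSeries

__all__ = [
    "ConditionPreset",
    "load_presets",
    "generate_connectome",
    "connectome_basis",
    "generate_timeseries",
    "generate_study",
]


@dataclass(frozen=True)
class ConditionPreset:
    """Per-condition parameters of the synthetic spectral profile."""

    name: str
    integration_sd: float
    gradient_sd: float
    tail_sd: float
    tail_decay: float
    noise_sd: float
    arousal_score: int

    def __post_init__(self) -> None:
        for attr in ("integration_sd", "gradient_sd", "tail_sd", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ParameterError(f"{attr} must be non-negative")
        if not 0 <= self.arousal_score <= 11:
            raise ParameterError("arousal_score must lie in [0, 11]")

    def mode_sds(self, n_modes: int) -> np.ndarray:
        """Per-mode coefficient standard deviations sigma_k (length N).

        sigma_1 = integration_sd; sigma_2 = sigma_3 = gradient_sd; the
        tail decays exponentially with mode index.
        """
        if n_modes < 4:
            raise ParameterError("need at least 4 modes for a spectral profile")
        sds = np.empty(n_modes)
        sds[0] = self.integration_sd
        sds[1:3] = self.gradient_sd
        k = np.arange(3, n_modes)
        sds[3:] = self.tail_sd * np.exp(
            -self.tail_decay * (k - 3) / max(n_modes - 3, 1)
        )
        return sds


def load_presets() -> dict[str, ConditionPreset]:
    """The packaged condition presets, keyed by condition name."""
    text = resources.files("eigenmarkers.resources").joinpath(
        "condition_presets.json"
    ).read_text()
    raw = json.loads(text)["presets"]
    return {name: ConditionPreset(name=name, **params) for name, params in raw.items()}


def generate_connectome(
    n_regions: int = 82,
    n_modules: int = 4,
    within_strength: float = 1.0,
    between_strength: float = 0.1,
    weight_noise: float = 0.2,
    seed: int | None = None,
    within_prob: float = 0.9,
    between_prob: float = 0.3,
) -> StructuralConnectome:
    """Weighted modular graph standing in for a tract-tracing connectome.

    Regions are split into ``n_modules`` near-equal modules; edges occur
    with probability ``within_prob``/``between_prob`` and carry lognormal
    weights around ``within_strength``/``between_strength``.  If the draw
    is disconnected, minimal bridge edges are added with a warning.
    """
    if n_regions < 4:
        raise ParameterError("need at least 4 regions")
    if not (within_strength > 0 and between_strength > 0):
        raise ParameterError("strengths must be positive")
    if within_strength <= between_strength:
        raise ParameterError("within_strength must exceed between_strength")
    rng = np.random.default_rng(seed)
    modules = np.concatenate(
        [np.full(len(chunk), m) for m, chunk in
         enumerate(np.array_split(np.arange(n_regions), n_modules))]
    )
    weights = np.zeros((n_regions, n_regions))
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            same = modules[i] == modules[j]
            prob = within_prob if same else between_prob
            base = within_strength if same else between_strength
            if rng.random() < prob:
                w = base * rng.lognormal(mean=0.0, sigma=weight_noise)
                weights[i, j] = weights[j, i] = w

    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, assignment = connected_components(
        csr_matrix(weights > 0), directed=False
    )
    if n_comp > 1:
        warnings.warn(
            f"generated graph had {n_comp} components; adding bridge edges",
            RegeneratedGraphWarning,
            stacklevel=2,
        )
        for comp in range(1, n_comp):
            a = int(np.flatnonzero(assignment == 0)[0])
            b = int(np.flatnonzero(assignment == comp)[0])
            weights[a, b] = weights[b, a] = between_strength
    labels = tuple(f"roi_{i:03d}" for i in range(n_regions))
    return symmetrize_connectome(weights, region_labels=labels)


def connectome_basis(sc: StructuralConnectome) -> HarmonicBasis:
    """Harmonic basis of a connectome (Laplacian eigendecomposition)."""
    return compute_harmonic_basis(
        build_normalized_laplacian(sc), region_labels=sc.region_labels
    )


def generate_timeseries(
    basis: HarmonicBasis,
    preset: ConditionPreset,
    n_timepoints: int = 500,
    tr: float = 1.25,
    seed: int | None = None,
    meta: dict | None = None,
) -> ParcellatedTimeSeries:
    """One synthetic run: Gaussian mode mixture plus isotropic noise."""
    if n_timepoints < 100:
        raise ParameterError("need at least 100 timepoints")
    n = basis.n_modes
    sds = preset.mode_sds(n)
    rng = np.random.default_rng(seed)
    omega = rng.normal(size=(n_timepoints, n)) * sds[None, :]
    data = omega @ basis.eigenvectors.T
    if preset.noise_sd > 0:
        data = data + rng.normal(scale=preset.noise_sd, size=data.shape)
    run_meta = {"condition": preset.name, "seed": seed}
    if meta:
        run_meta.update(meta)
    return ParcellatedTimeSeries(
        data=data, tr=tr, region_labels=basis.region_labels, meta=run_meta
    )


def generate_study(
    out_dir,
    presets=None,
    runs_per_condition: int = 4,
    animals=("m01", "m02", "m03"),
    seed: int | None = None,
    n_regions: int = 82,
    n_timepoints: int = 500,
    tr: float = 1.25,
    dataset: str = "synthetic",
) -> Path:
    """Write a complete on-disk dataset in the pipeline's input layout.

    Layout: ``connectome.tsv``, ``runs/<condition>_<animal>_<run>.tsv``
    with JSON sidecars, and ``arousal.csv`` (condition, arousal_score).
    Animal labels are cycled over runs.  Deterministic under ``seed``.
    """
    if presets is None:
        presets = load_presets()
    if isinstance(presets, dict):
        presets = list(presets.values())
    if len(presets) < 2:
        raise ParameterError("need at least 2 conditions")
    out_dir = Path(out_dir)
    (out_dir / "runs").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    connectome_seed = int(master.integers(2**31))
    sc = generate_connectome(n_regions=n_regions, seed=connectome_seed)
    basis = connectome_basis(sc)
    write_connectome_tsv(sc, out_dir / "connectome.tsv")

    for preset in presets:
        for run_idx in range(runs_per_condition):
            animal = animals[run_idx % len(animals)]
            run_seed = int(master.integers(2**31))
            ts = generate_timeseries(
                basis,
                preset,
                n_timepoints=n_timepoints,
                tr=tr,
                seed=run_seed,
                meta={
                    "dataset": dataset,
                    "animal": animal,
                    "run": f"run{run_idx + 1:02d}",
                },
            )
            stem = f"{preset.name}_{animal}_run{run_idx + 1:02d}"
            write_timeseries_tsv(ts, out_dir / "runs" / f"{stem}.tsv")

    arousal = pd.DataFrame(
        {
            "condition": [p.name for p in presets],
            "arousal_score": [p.arousal_score for p in presets],
        }
    )
    arousal.to_csv(out_dir / "arousal.csv", index=False)
    return out_dir
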