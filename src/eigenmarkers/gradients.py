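"""Functional gradients from diffusion map embedding of FC similarity.

Pipeline: Pearson functional connectivity -> Fisher z -> row-wise
sparsification to a target density -> cosine-family similarity between
sparsified connectivity profiles -> anisotropic diffusion map embedding.
Each embedding component ("gradient") is one axis of variation in
regional connectivity profiles; regions with similar FC profiles land
close together.  Scan-level markers:

* gradient range  — max minus min of a component (depth of the axis);
* gradient dispersion — summed squared distance to the centroid in the
  first three gradients;
* principal eigenvalue ratio — share of the first embedding eigenvalue.

All three are invariant to component sign and to region relabelling, so
no cross-scan alignment is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegenerateInputError, DisconnectedGraphError, ParameterError
from .harmonics import fix_eigenvector_signs
from .preprocessing import ParcellatedTimeSeries

__all__ = [
    "FunctionalConnectivity",
    "GradientEmbedding",
    "compute_fc",
    "build_affinity",
    "diffusion_map_embedding",
    "gradient_range",
    "gradient_dispersion",
    "principal_eigenvalue_ratio",
]

#: |r| is clipped here before the Fisher transform so atanh stays finite.
_FISHER_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FunctionalConnectivity:
    """Region x region Pearson correlation matrix."""

    matrix: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError("FC must be square")
        if len(self.region_labels) != m.shape[0]:
            raise ParameterError("region label count does not match FC size")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class GradientEmbedding:
    """Low-dimensional diffusion-map coordinates of regions.

    ``gradients`` is N x m, columns ordered by descending embedding
    eigenvalue; ``eigenvalues`` are the m retained (non-trivial) Markov
    eigenvalues.  The constant eigenvalue-1 mode is excluded.
    """

    gradients: np.ndarray
    eigenvalues: np.ndarray
    params: dict = field(default_factory=dict)
    region_labels: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.gradients.shape[1]


def compute_fc(ts: ParcellatedTimeSeries) -> FunctionalConnectivity:
    """Pearson correlation between every pair of regional series."""
    if ts.n_timepoints < 3:
        raise ParameterError("FC needs at least 3 timepoints")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.region_labels[i] for i in dead]
        raise DegenerateInputError(f"zero-variance regions: {names}")
    fc = np.corrcoef(ts.data, rowvar=False)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return FunctionalConnectivity(matrix=fc, region_labels=ts.region_labels)


def _row_threshold(z: np.ndarray, density: float) -> np.ndarray:
    """Keep the k = round(density * (N-1)) largest signed entries per row.

    Ties break toward the lower column index.  The result is generally
    asymmetric; symmetry is restored by the similarity kernel applied to
    its rows.
    """
    n = z.shape[0]
    k = int(np.round(density * (n - 1)))
    if k < 1:
        raise ParameterError(
            f"density {density} keeps no entries per row for N={n}"
        )
    out = np.zeros_like(z)
    for i in range(n):
        order = np.argsort(-z[i], kind="stable")
        keep = order[order != i][:k]
        out[i, keep] = z[i, keep]
    return out


def _cosine_rows(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("zero-norm row after thresholding")
    cos = (rows @ rows.T) / np.outer(norms, norms)
    return np.clip(cos, -1.0, 1.0)


def build_affinity(
    fc: FunctionalConnectivity,
    density: float = 0.10,
    kernel: str = "normalized_angle",
) -> np.ndarray:
    """Similarity between sparsified Fisher-z connectivity profiles.

    The FC is Fisher z-transformed off-diagonally (diagonal set to 0),
    each row keeps only its strongest ``density`` fraction of entries,
    and the affinity between regions i and j is the kernel similarity of
    their thresholded rows: ``normalized_angle`` maps the angle between
    profiles to [0, 1]; ``cosine`` is the raw cosine clipped at 0 to keep
    the affinity non-negative.
    """
    if not 0 < density <= 1:
        raise ParameterError(f"density must be in (0, 1], got {density}")
    if kernel not in ("normalized_angle", "cosine"):
        raise ParameterError(f"unknown kernel {kernel!r}")
    r = np.clip(fc.matrix, -_FISHER_CLIP, _FISHER_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    rows = _row_threshold(z, density)
    cos = _cosine_rows(rows)
    if kernel == "normalized_angle":
        affinity = 1.0 - np.arccos(cos) / np.pi
    else:
        affinity = np.clip(cos, 0.0, None)
    affinity = (affinity + affinity.T) / 2.0
    np.fill_diagonal(affinity, 1.0)
    return affinity


def diffusion_map_embedding(
    affinity: np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
    diffusion_time: float = 0,
    region_labels=None,
) -> GradientEmbedding:
    """Anisotropic diffusion map embedding of a non-negative affinity.

    With W the affinity and d its row sums, the alpha-normalised kernel
    W' = D^{-alpha} W D^{-alpha} (alpha = 0.5 balances local and global
    geometry) is row-normalised into a Markov matrix P whose spectrum is
    obtained through the symmetric conjugate.  The trivial constant
    eigenvector (eigenvalue 1) is dropped; component k is the k-th right
    eigenvector of P scaled by lambda_k / (1 - lambda_k) at
    ``diffusion_time`` 0 (the multi-scale convention) or by
    lambda_k ** diffusion_time otherwise.
    """
    w = np.asarray(affinity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ParameterError("affinity must be square")
    if np.any(w < 0):
        raise ParameterError("affinity must be non-negative")
    if np.max(np.abs(w - w.T)) > 1e-10:
        raise ParameterError("affinity must be symmetric")
    if not 0 <= alpha <= 1:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    n = w.shape[0]
    if not 1 <= n_components <= n - 1:
        raise ParameterError(f"n_components must be in [1, {n - 1}]")

    d = w.sum(axis=1)
    if np.any(d <= 0):
        raise DisconnectedGraphError("affinity has an all-zero row")
    d_alpha = d**alpha
    w_alpha = w / np.outer(d_alpha, d_alpha)
    d2 = w_alpha.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    sym = w_alpha * np.outer(inv_sqrt, inv_sqrt)
    sym = (sym + sym.T) / 2.0
    evals, evecs = scipy.linalg.eigh(sym)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if n > 1 and evals[1] > 1.0 - 1e-10:
        raise DisconnectedGraphError(
            "affinity graph is disconnected (eigenvalue 1 has multiplicity > 1)"
        )
    # Right eigenvectors of the Markov matrix, normalised so the trivial
    # mode is the constant vector (divide by the stationary eigenvector).
    psi = evecs / evecs[:, [0]]
    lam = evals[1 : n_components + 1]
    comp = psi[:, 1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    gradients = fix_eigenvector_signs(comp * scale[None, :])
    if region_labels is None:
        region_labels = tuple(f"roi_{i:03d}" for i in range(n))
    return GradientEmbedding(
        gradients=gradients,
        eigenvalues=lam,
        params={
            "alpha": alpha,
            "n_components": n_components,
            "diffusion_time": diffusion_time,
        },
        region_labels=tuple(region_labels),
    )


def gradient_range(emb: GradientEmbedding, k: int = 1) -> float:
    """Max minus min of gradient ``k`` (1-based component index)."""
    if not 1 <= k <= emb.n_components:
        raise ParameterError(f"component {k} out of range 1..{emb.n_components}")
    col = emb.gradients[:, k - 1]
    return float(col.max() - col.min())


def gradient_dispersion(emb: GradientEmbedding, m: int = 3) -> float:
    """Sum of squared distances of regions to the centroid of the
    first ``m`` gradients."""
    if m > emb.n_components:
        raise ParameterError(
            f"requested {m} components but embedding has {emb.n_components}"
        )
    coords = emb.gradients[:, :m]
    centred = coords - coords.mean(axis=0, keepdims=True)
    return float((centred**2).sum())


def principal_eigenvalue_ratio(emb: GradientEmbedding) -> float:
    """First embedding eigenvalue over the sum of the retained ones."""
    lam = np.asarray(emb.eigenvalues, dtype=float)
    if lam.size == 0:
        raise ParameterError("embedding has no eigenvalues")
    total = lam.sum()
    if total <= 0:
        raise DegenerateInputError("non-positive eigenvalue sum")
    return float(lam[0] / total)
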