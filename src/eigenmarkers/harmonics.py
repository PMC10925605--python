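"""Harmonic mode decomposition of BOLD activity on a structural connectome.

The structural connectome (a symmetric, non-negative region x region
weight matrix C) defines a graph whose symmetric normalised Laplacian

    L_sym = D^{-1/2} (D - C) D^{-1/2},   D(i,i) = sum_j C(i,j)

has an orthonormal eigenbasis of *harmonic modes* phi_k with eigenvalues
0 = lambda_1 <= lambda_2 <= ... <= lambda_N <= 2.  Low-lambda modes are
spatially smooth whole-cortex patterns; high-lambda modes are fine-grained.
Each BOLD timepoint F_t (a length-N activity pattern) is expanded on this
basis, omega_k(t) = <F_t, phi_k>; the *power* of mode k is |omega_k(t)|
and its *energy* is omega_k(t)^2 * lambda_k^2, weighting each mode's
contribution by its intrinsic spatial frequency.  Summed over modes and
averaged over time, the energy quantifies how strongly ongoing activity is
shaped by high-spatial-frequency structure of the anatomical network: the
uniform mode (lambda = 0) carries zero energy by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    AlignmentError,
    DegenerateEigenvalueWarning,
    DegenerateInputError,
    DisconnectedGraphError,
    ParameterError,
)
from .preprocessing import ParcellatedTimeSeries

__all__ = [
    "StructuralConnectome",
    "HarmonicBasis",
    "HarmonicSpectrum",
    "symmetrize_connectome",
    "build_normalized_laplacian",
    "compute_harmonic_basis",
    "decompose_timeseries",
    "scan_energy",
    "fix_eigenvector_signs",
]


def fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties are resolved toward the lowest row index (``argmax`` takes the
    first maximum).  This gives eigendecompositions a reproducible sign
    without affecting any quadratic quantity built from them.
    """
    vectors = np.array(vectors, dtype=float, copy=True)
    for k in range(vectors.shape[1]):
        idx = int(np.argmax(np.abs(vectors[:, k])))
        if vectors[idx, k] < 0:
            vectors[:, k] = -vectors[:, k]
    return vectors


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric non-negative region x region connection weights."""

    weights: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError(f"connectome must be square, got {w.shape}")
        if len(self.region_labels) != w.shape[0]:
            raise ParameterError("region label count does not match matrix size")
        if not np.all(np.isfinite(w)):
            raise ParameterError("connectome contains non-finite weights")
        if np.any(w < 0):
            raise ParameterError("connectome weights must be non-negative")
        if np.max(np.abs(w - w.T)) != 0:
            raise ParameterError("connectome must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise ParameterError("connectome diagonal must be zero")
        _check_connected(w, self.region_labels)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class HarmonicBasis:
    """Orthonormal Laplacian eigenvectors with ascending eigenvalues."""

    eigenvectors: np.ndarray  # N x N, column k = phi_k
    eigenvalues: np.ndarray  # ascending, lambda_1 ~ 0
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "eigenvectors", np.asarray(self.eigenvectors, float))
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, float))
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Per-timepoint projection of BOLD onto the harmonic basis.

    ``coefficients`` is T x N with omega_k(t) in column k; ``power`` is
    |omega| and ``energy`` is omega^2 * lambda^2 (both T x N).
    """

    coefficients: np.ndarray
    eigenvalues: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def energy(self) -> np.ndarray:
        return self.coefficients**2 * self.eigenvalues[None, :] ** 2

    @property
    def mode_energy(self) -> np.ndarray:
        """Time-averaged energy per mode (length N)."""
        return self.energy.mean(axis=0)


def _check_connected(weights: np.ndarray, labels: tuple[str, ...]) -> None:
    n_comp, assignment = connected_components(csr_matrix(weights > 0), directed=False)
    if n_comp > 1:
        counts = np.bincount(assignment)
        smallest = int(np.argmin(counts))
        members = [labels[i] for i in np.flatnonzero(assignment == smallest)]
        raise DisconnectedGraphError(
            f"connectome graph has {n_comp} components; smallest component: "
            f"{members}"
        )
    if np.any(weights.sum(axis=1) <= 0):
        isolated = [labels[i] for i in np.flatnonzero(weights.sum(axis=1) <= 0)]
        raise DisconnectedGraphError(f"isolated regions with zero degree: {isolated}")


def symmetrize_connectome(
    raw: np.ndarray, region_labels=None
) -> StructuralConnectome:
    """Average mirror entries of a possibly directed weight matrix.

    Returns ``(raw + raw.T) / 2`` with the diagonal forced to zero,
    wrapped as a validated :class:`StructuralConnectome` (the constructor
    checks symmetry, non-negativity and connectivity).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ParameterError(f"connectome must be square, got {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ParameterError("connectome contains non-finite weights")
    if np.any(raw < 0):
        raise ParameterError("connectome weights must be non-negative")
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    if region_labels is None:
        region_labels = tuple(f"roi_{i:03d}" for i in range(raw.shape[0]))
    return StructuralConnectome(weights=sym, region_labels=region_labels)


def build_normalized_laplacian(sc: StructuralConnectome) -> np.ndarray:
    """Symmetric normalised graph Laplacian D^{-1/2} (D - C) D^{-1/2}.

    Unit diagonal; eigenvalues lie in [0, 2] with 0 attained exactly once
    for a connected graph.
    """
    deg = sc.degrees
    if np.any(deg <= 0):
        raise DisconnectedGraphError("zero-degree region: cannot normalise")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lap = -sc.weights * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(lap, 1.0)
    return (lap + lap.T) / 2.0  # kill round-off asymmetry


def compute_harmonic_basis(
    laplacian: np.ndarray, region_labels=None
) -> HarmonicBasis:
    """Full eigendecomposition of a symmetric Laplacian, ascending order.

    All N modes are returned; the first has eigenvalue 0 (the uniform-sign
    mode, proportional to D^{1/2} 1 for a connected graph).  Eigenvector
    signs follow :func:`fix_eigenvector_signs`.  Within a degenerate
    eigenvalue the returned eigenvectors are one valid orthonormal choice;
    aggregate power/energy quantities do not depend on that choice.
    """
    laplacian = np.asarray(laplacian, dtype=float)
    if laplacian.ndim != 2 or laplacian.shape[0] != laplacian.shape[1]:
        raise ParameterError("laplacian must be square")
    if np.max(np.abs(laplacian - laplacian.T)) > 1e-10:
        raise ParameterError("laplacian must be symmetric")
    eigenvalues, eigenvectors = scipy.linalg.eigh(laplacian)
    eigenvectors = fix_eigenvector_signs(eigenvectors)
    if region_labels is None:
        region_labels = tuple(f"roi_{i:03d}" for i in range(laplacian.shape[0]))
    return HarmonicBasis(
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        region_labels=region_labels,
    )


def decompose_timeseries(
    ts: ParcellatedTimeSeries, basis: HarmonicBasis
) -> HarmonicSpectrum:
    """Project every timepoint onto the harmonic basis.

    omega(t) = Phi^T F_t for each row F_t of the data; since Phi is
    orthonormal the expansion is exact and Parseval holds per timepoint:
    sum_k omega_k(t)^2 = ||F_t||^2.
    """
    if ts.n_regions != basis.n_modes:
        raise AlignmentError(
            f"time series has {ts.n_regions} regions but basis has "
            f"{basis.n_modes} modes"
        )
    if ts.region_labels != basis.region_labels:
        raise AlignmentError("region labels of time series and basis differ")
    coefficients = ts.data @ basis.eigenvectors  # T x N
    return HarmonicSpectrum(
        coefficients=coefficients,
        eigenvalues=basis.eigenvalues,
        meta=dict(ts.meta),
    )


def scan_energy(spectrum: HarmonicSpectrum) -> float:
    """Scan-level harmonic energy: mean over time of the summed mode energy.

    Zero exactly when the signal lives entirely in the lambda = 0 uniform
    mode; grows as variance moves into high-spatial-frequency modes.
    """
    if spectrum.coefficients.size == 0:
        raise DegenerateInputError("empty harmonic spectrum")
    return float(spectrum.energy.sum(axis=1).mean())


def warn_if_degenerate(eigenvalues: np.ndarray, tol: float = 1e-10) -> None:
    """Emit a warning when consecutive eigenvalues are numerically tied."""
    gaps = np.diff(np.sort(np.asarray(eigenvalues, float)))
    if np.any(np.abs(gaps) < tol):
        warnings.warn(
            "near-degenerate eigenvalues: eigenvector-dependent output is "
            "solver-dependent within the tied subspace",
            DegenerateEigenvalueWarning,
            stacklevel=3,
        )
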