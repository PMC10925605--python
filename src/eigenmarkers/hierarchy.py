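"""Hierarchical integration and segregation from FC eigenmodes.

A symmetric functional connectivity matrix decomposes as FC = U L U^T.
Each eigenvector partitions regions into a same-sign group and an
opposite-sign group; applying the eigenvectors in descending-eigenvalue
order and splitting every existing module by the sign of the next
eigenvector yields a *nested sign partition*: level 1 is one whole-cortex
module, and generic inputs reach all-singleton modules.  With M_i the
module count at level i, module sizes m_j, and the size-heterogeneity
correction

    p_i = sum_j |m_j - N / M_i| / N,

the markers are

    H_In = L_1^2 * M_1 * (1 - p_1) / N^2 = L_1^2 / N^2
    H_Se = sum_{i>=2} L_i^2 * M_i * (1 - p_i) / N^2.

H_In is the covariance share of the global (single-module) mode; H_Se
accumulates all partitioning modes, each weighted by how many modules it
creates and down-weighted when module sizes are uneven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import ParameterError
from .gradients import FunctionalConnectivity
from .harmonics import fix_eigenvector_signs, warn_if_degenerate

__all__ = [
    "HierarchyDecomposition",
    "fc_eigenmodes",
    "nested_sign_partition",
    "size_correction_factor",
    "hierarchical_integration",
    "hierarchical_segregation",
    "decompose_hierarchy",
]


@dataclass(frozen=True)
class HierarchyDecomposition:
    """Eigenmodes of FC plus the nested sign-partition hierarchy.

    ``eigenvalues`` are descending (tiny negative values clamped to 0
    before squaring); ``levels`` holds, per level i, the list of module
    index-arrays; ``module_counts``/``module_sizes``/``corrections`` are
    the M_i, (m_j), p_i summaries; ``h_in``/``h_se`` the two markers.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    levels: tuple
    module_counts: tuple[int, ...]
    module_sizes: tuple
    corrections: tuple[float, ...]
    h_in: float
    h_se: float


def _as_matrix(fc) -> np.ndarray:
    if isinstance(fc, FunctionalConnectivity):
        fc = fc.matrix
    m = np.asarray(fc, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError("FC must be a square matrix")
    if np.max(np.abs(m - m.T)) > 1e-10:
        raise ParameterError("FC must be symmetric")
    return (m + m.T) / 2.0


def fc_eigenmodes(fc) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of FC, sorted by descending eigenvalue.

    Returns ``(eigenvalues, eigenvectors)`` with a deterministic sign
    convention; emits a warning when consecutive eigenvalues are tied to
    within 1e-10 (the partition is then solver-dependent).
    """
    m = _as_matrix(fc)
    evals, evecs = scipy.linalg.eigh(m)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    warn_if_degenerate(evals)
    return evals, fix_eigenvector_signs(evecs)


def nested_sign_partition(u: np.ndarray, n_levels: int | None = None) -> list:
    """Recursive sign-based split of modules by successive eigenvectors.

    Level 1 is the single whole-cortex module.  At level i >= 2 every
    level-(i-1) module is split into its non-negative-sign and
    negative-sign subsets under eigenvector i (exact zeros group with +);
    empty subsets are dropped, so a module may pass through unsplit.
    Returns a list of levels, each a list of region-index arrays.
    """
    u = np.asarray(u, dtype=float)
    n = u.shape[0]
    if n_levels is None:
        n_levels = n
    modules = [np.arange(n)]
    levels = [[m.copy() for m in modules]]
    for i in range(1, n_levels):
        vec = u[:, i]
        nxt = []
        for mod in modules:
            pos = mod[vec[mod] >= 0]
            neg = mod[vec[mod] < 0]
            if pos.size:
                nxt.append(pos)
            if neg.size:
                nxt.append(neg)
        modules = nxt
        levels.append([m.copy() for m in modules])
    return levels


def size_correction_factor(sizes, n: int) -> float:
    """Deviation of module sizes from homogeneity: sum |m_j - N/M| / N."""
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        raise ParameterError("empty module-size list")
    if sizes.sum() != n:
        raise ParameterError(f"module sizes sum to {sizes.sum()}, expected {n}")
    m_count = sizes.size
    return float(np.abs(sizes - n / m_count).sum() / n)


def hierarchical_integration(decomp: HierarchyDecomposition) -> float:
    """Covariance share of the global mode: L_1^2 / N^2."""
    return decomp.h_in


def hierarchical_segregation(decomp: HierarchyDecomposition) -> float:
    """Summed size-corrected, module-weighted share of all non-global
    modes: sum_{i>=2} L_i^2 M_i (1 - p_i) / N^2."""
    return decomp.h_se


def decompose_hierarchy(fc) -> HierarchyDecomposition:
    """Full pipeline: eigenmodes, nested partition, H_In and H_Se."""
    evals, evecs = fc_eigenmodes(fc)
    n = evals.size
    clamped = np.clip(evals, 0.0, None)  # kill tiny negative round-off
    levels = nested_sign_partition(evecs)
    counts = tuple(len(level) for level in levels)
    sizes = tuple(tuple(int(m.size) for m in level) for level in levels)
    corrections = tuple(size_correction_factor(s, n) for s in sizes)
    weights = np.array(
        [counts[i] * (1.0 - corrections[i]) for i in range(n)], dtype=float
    )
    terms = clamped**2 * weights / n**2
    h_in = float(terms[0])
    h_se = float(terms[1:].sum())
    return HierarchyDecomposition(
        eigenvalues=evals,
        eigenvectors=evecs,
        levels=tuple(tuple(m for m in level) for level in levels),
        module_counts=counts,
        module_sizes=sizes,
        corrections=corrections,
        h_in=h_in,
        h_se=h_se,
    )
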