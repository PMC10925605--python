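"""Plain-text readers and writers for the dataset layout.

Everything is TSV or JSON so datasets diff cleanly and carry no binary
dependencies:

* time series: TSV, rows = timepoints, header row = region labels, with
  a JSON sidecar ``{tr_s, dataset, animal, condition, run, ...}``;
* connectome / FC / affinity: square TSV with a region-label header row
  and a leading label column;
* harmonic basis: TSV of modes-as-columns plus a JSON eigenvalue list;
* a dataset directory: ``connectome.tsv``, ``runs/*.tsv`` (+ ``.json``
  sidecars), ``arousal.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocessing import ParcellatedTimeSeries

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_connectome_tsv",
    "write_connectome_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_basis",
    "list_dataset_runs",
    "read_arousal_csv",
]

_SIDECAR_KEYS = ("dataset", "animal", "condition", "run")


def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(".json")


def write_timeseries_tsv(ts: ParcellatedTimeSeries, path) -> Path:
    """Write a run as TSV plus JSON sidecar next to it."""
    path = Path(path)
    df = pd.DataFrame(ts.data, columns=list(ts.region_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {"tr_s": ts.tr}
    for key in _SIDECAR_KEYS:
        if key in ts.meta:
            sidecar[key] = ts.meta[key]
    extra = {k: v for k, v in ts.meta.items() if k not in _SIDECAR_KEYS}
    sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_timeseries_tsv(path) -> ParcellatedTimeSeries:
    """Read a run TSV and its JSON sidecar."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ParameterError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    if "tr_s" not in sidecar:
        raise ParameterError(f"sidecar {sidecar_file} lacks tr_s")
    tr = float(sidecar.pop("tr_s"))
    return ParcellatedTimeSeries(
        data=df.to_numpy(dtype=float),
        tr=tr,
        region_labels=tuple(df.columns),
        meta=sidecar,
    )


def write_matrix_tsv(matrix: np.ndarray, labels, path) -> Path:
    """Square labelled matrix as TSV (header row + leading label column)."""
    path = Path(path)
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_matrix_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParameterError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_connectome_tsv(sc, path) -> Path:
    return write_matrix_tsv(sc.weights, sc.region_labels, path)


def read_connectome_tsv(path):
    from .harmonics import StructuralConnectome

    weights, labels = read_matrix_tsv(path)
    return StructuralConnectome(weights=weights, region_labels=labels)


def write_basis(basis, path_prefix) -> tuple[Path, Path]:
    """Harmonic basis as <prefix>.tsv (modes as columns) and
    <prefix>_eigenvalues.json."""
    prefix = Path(path_prefix)
    df = pd.DataFrame(
        basis.eigenvectors,
        index=list(basis.region_labels),
        columns=[f"mode_{k + 1:03d}" for k in range(basis.n_modes)],
    )
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", float_format="%.10g")
    ev = prefix.parent / f"{prefix.stem}_eigenvalues.json"
    ev.write_text(json.dumps(list(map(float, basis.eigenvalues))))
    return tsv, ev


def list_dataset_runs(dataset_dir) -> list[Path]:
    """Run TSVs of a dataset directory, sorted for determinism."""
    runs_dir = Path(dataset_dir) / "runs"
    if not runs_dir.is_dir():
        raise ParameterError(f"no runs/ directory under {dataset_dir}")
    return sorted(runs_dir.glob("*.tsv"))


def read_arousal_csv(dataset_dir) -> dict[str, int]:
    """Condition -> arousal score map from a dataset's arousal.csv."""
    path = Path(dataset_dir) / "arousal.csv"
    if not path.exists():
        raise ParameterError(f"missing {path}")
    df = pd.read_csv(path)
    if not {"condition", "arousal_score"} <= set(df.columns):
        raise ParameterError(f"{path} needs condition and arousal_score columns")
    return dict(zip(df["condition"], df["arousal_score"].astype(int)))
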