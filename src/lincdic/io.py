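"""Readers, writers, and the packaged protein-signaling fixtures.

All user-facing interfaces are name-based: the header of the data CSV defines
the variable order, and constraint tables refer to variables by those names.
Zero-based indices exist only inside the numeric core.

File formats
------------
data CSV
    header of ``d`` unique names, ``n`` numeric rows;
weight CSV
    ``d × d`` matrix with the names on both axes (index column + header);
constraint TSV
    columns ``cause  target  kind  delta`` with ``kind ∈ {+, -, path}``; an
    empty delta means the default ``±0.01`` (interventional) or the default
    reachability margin (path rows).

Packaged fixtures cover the flow-cytometry protein-signaling benchmark (11
phosphoproteins/phospholipids in human immune cells): the eight
literature-curated interventional constraints and the 20-edge consensus
network used as the reference graph.  The 853×11 observational data file is
not bundled; ``expected_sachs_layout`` documents what to supply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import InterventionalConstraint, validate_constraints
from .reachability import PathConstraint
from .synthetic import DEFAULT_DELTA, GroundTruth

__all__ = [
    "Dataset",
    "read_dataset",
    "read_weights",
    "write_weights",
    "write_edges",
    "read_constraints",
    "sachs_constraints_path",
    "sachs_benchmark_graph",
    "SACHS_VARIABLES",
    "load_sachs_dataset",
    "training_subsets",
]

#: canonical variable names of the flow-cytometry benchmark (853 × 11)
SACHS_VARIABLES = [
    "Raf", "Mek", "Plcg", "PIP2", "PIP3", "Erk", "Akt", "PKA", "PKC", "P38", "Jnk",
]

#: aliases used by common distributions of the dataset
_SACHS_ALIASES = {
    "praf": "Raf", "pmek": "Mek", "plcg": "Plcg", "pip2": "PIP2",
    "pip3": "PIP3", "p44.42": "Erk", "p44/42": "Erk", "erk": "Erk",
    "pakts473": "Akt", "akt": "Akt", "pka": "PKA", "pkc": "PKC",
    "p38": "P38", "pjnk": "Jnk", "jnk": "Jnk", "raf": "Raf", "mek": "Mek",
}

_FLOAT_FMT = "%.17g"


@dataclass
class Dataset:
    """Observation matrix with its variable names."""

    X: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not self.variable_names:
            self.variable_names = [f"X{i + 1}" for i in range(self.X.shape[1])]
        if len(self.variable_names) != self.X.shape[1]:
            raise ValueError("variable_names length must match column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown variable {name!r}; dataset has {self.variable_names}"
            ) from None


def read_dataset(path) -> Dataset:
    """Read a headered numeric CSV into a :class:`Dataset`.

    Duplicate header names, non-numeric cells and missing values are rejected
    with the offending row/column named.
    """
    # read the raw header first: pandas would silently mangle duplicates
    raw = pd.read_csv(path, header=None, nrows=1).iloc[0].tolist()
    names = [str(c) for c in raw]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate column names in {path}: {sorted(dupes)}")
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = names
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {df[col][row]!r} at row {row}, column {col!r}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = numeric
    if df.shape[0] < 1 or df.shape[1] < 2:
        raise ValueError(f"dataset must be at least 1 x 2, got {df.shape}")
    return Dataset(df.to_numpy(dtype=float), names)


def write_dataset(ds: Dataset, path) -> None:
    pd.DataFrame(ds.X, columns=ds.variable_names).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_weights(path) -> tuple[np.ndarray, list[str]]:
    """Read a named ``d × d`` weight matrix CSV (index column + header)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    names = [str(c) for c in df.columns]
    if list(map(str, df.index)) != names:
        raise ValueError(f"weight matrix in {path} has mismatched axis names")
    return df.to_numpy(dtype=float), names


def write_weights(W, names: Sequence[str], path) -> None:
    W = np.asarray(W, dtype=float)
    pd.DataFrame(W, index=list(names), columns=list(names)).to_csv(
        path, float_format=_FLOAT_FMT
    )


def write_edges(W, names: Sequence[str], path) -> None:
    """Write the nonzero entries as a ``source  target  weight`` TSV."""
    W = np.asarray(W, dtype=float)
    rows = [
        (names[i], names[j], W[i, j])
        for i, j in zip(*np.nonzero(W))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_constraints(
    path, names: Sequence[str], *, default_delta: float = DEFAULT_DELTA,
    default_margin: float = 0.01,
) -> tuple[list[InterventionalConstraint], list[PathConstraint]]:
    """Parse a constraint TSV against the dataset's variable names.

    ``+``/``-`` rows become interventional constraints with
    ``delta = ±default_delta`` unless the row carries an explicit delta;
    ``path`` rows become reachability constraints.  Unknown names, self
    loops, and sign-contradictory duplicates are rejected.
    """
    names = list(names)
    df = pd.read_csv(path, sep="\t", dtype={"cause": str, "target": str, "kind": str})
    required = {"cause", "target", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"constraint file {path} must have columns {sorted(required)}"
        )
    interventional: list[InterventionalConstraint] = []
    paths: list[PathConstraint] = []
    for row in df.itertuples(index=True):
        for name in (row.cause, row.target):
            if name not in names:
                raise ValueError(
                    f"row {row.Index}: unknown variable {name!r} "
                    f"(dataset has {names})"
                )
        i, j = names.index(row.cause), names.index(row.target)
        if i == j:
            raise ValueError(f"row {row.Index}: self-loop constraint on {row.cause!r}")
        value = getattr(row, "delta", None)
        has_value = value is not None and not pd.isna(value)
        kind = str(row.kind).strip()
        if kind == "+":
            delta = float(value) if has_value else default_delta
            if delta <= 0:
                raise ValueError(f"row {row.Index}: '+' row needs a positive delta")
            interventional.append(InterventionalConstraint(i, j, delta))
        elif kind in ("-", "−"):
            delta = float(value) if has_value else -default_delta
            if delta >= 0:
                raise ValueError(f"row {row.Index}: '-' row needs a negative delta")
            interventional.append(InterventionalConstraint(i, j, delta))
        elif kind == "path":
            margin = float(value) if has_value else default_margin
            paths.append(PathConstraint(i, j, margin))
        else:
            raise ValueError(f"row {row.Index}: unknown kind {kind!r}")
    validate_constraints(interventional, len(names))
    return interventional, paths


# ---------------------------------------------------------------------------
# ground-truth serialisation (generator side-car format)


def write_ground_truth(gt: GroundTruth, weights_path, sidecar_path=None) -> None:
    names = gt.variable_names or [f"X{i + 1}" for i in range(gt.d)]
    write_weights(gt.W_true, names, weights_path)
    if sidecar_path is not None:
        import json

        Path(sidecar_path).write_text(
            json.dumps(
                {
                    "graph_type": gt.graph_type,
                    "noise_scales": gt.noise_scales.tolist(),
                    "variable_names": names,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# protein-signaling benchmark fixtures


def sachs_constraints_path() -> Path:
    """Path of the packaged eight-row curated constraint table."""
    return Path(resources.files("lincdic") / "data" / "sachs_constraints.tsv")


def sachs_benchmark_graph() -> tuple[np.ndarray, list[str]]:
    """The 20-edge consensus signaling network as a 0/1 adjacency matrix."""
    path = Path(resources.files("lincdic") / "data" / "sachs_benchmark.csv")
    return read_weights(path)


def expected_sachs_layout() -> str:
    return (
        "a CSV of 853 rows x 11 columns with header names "
        f"{SACHS_VARIABLES} (common aliases such as praf/pmek/p44.42/"
        "pakts473/pjnk are recognised); the purely observational "
        "flow-cytometry condition of the benchmark"
    )


def load_sachs_dataset(path) -> Dataset:
    """Load a user-supplied observational file, canonicalising column names.

    Verifies the expected 853 × 11 shape and that all 11 protein names
    resolve; columns are reordered to the canonical order.
    """
    ds = read_dataset(path)
    canon = []
    for name in ds.variable_names:
        key = name.strip()
        canon.append(_SACHS_ALIASES.get(key.lower(), key))
    missing = [n for n in SACHS_VARIABLES if n not in canon]
    if missing:
        raise ValueError(
            f"file {path} lacks variables {missing}; expected {expected_sachs_layout()}"
        )
    order = [canon.index(n) for n in SACHS_VARIABLES]
    X = ds.X[:, order]
    if X.shape != (853, 11):
        raise ValueError(
            f"file {path} has shape {X.shape}; expected (853, 11)"
        )
    return Dataset(X, list(SACHS_VARIABLES))


def training_subsets(constraints: Sequence, k: int = 3) -> list[tuple]:
    """All size-``k`` training subsets for leave-out cross-validation.

    Eight curated constraints with ``k = 3`` give ``C(8, 3) = 56``
    combinations, enumerated in deterministic lexicographic order.
    """
    return list(itertools.combinations(list(constraints), k))
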