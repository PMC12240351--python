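"""Degree-based topological indices and their Shannon-type entropy counterparts.

Every index here has the edge-sum form ``T(G) = sum over edges uv of
phi(d_u, d_v)`` for a strictly positive, symmetric weight ``phi`` of the
endpoint degrees.  Because ``phi`` depends on the edge only through the
degree pair, the sum collapses onto the edge partition:

    T = sum over cells (i, j) of n_ij * phi(i, j)

The associated entropy index is the Shannon entropy of the weight
distribution p_e = phi_e / T over edges, computed in the numerically
convenient form

    Ent_phi = ln(T) - (1/T) * sum n_ij * phi(i, j) * ln(phi(i, j))

with natural logarithms throughout.  It satisfies 0 <= Ent_phi <= ln m,
with the upper bound attained exactly when all edge weights are equal
(for instance on any regular graph, for every index).

The ten weights implemented (ABC, F, GA, H, ISI, M1, M2, S, SO, R) are
the classical atom-bond-connectivity, forgotten, geometric-arithmetic,
harmonic, inverse-sum-indeg, first and second Zagreb, sum-connectivity,
Sombor and Randic indices.

One degenerate case exists: the ABC weight vanishes on a (1, 1) edge
(an isolated K2 component).  The corresponding entropy term phi*ln(phi)
is taken as 0 by continuity and a warning is issued; if *every* cell has
zero weight the entropy is undefined and an error is raised.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Iterable, Sequence

import pandas as pd

from .molgraph import EdgePartition

__all__ = [
    "INDEX_NAMES",
    "edge_weight",
    "topological_index",
    "entropy_index",
    "descriptor_matrix",
    "entropy_column",
    "topological_column",
]

_WEIGHTS: dict[str, Callable[[int, int], float]] = {
    "ABC": lambda i, j: math.sqrt((i + j - 2) / (i * j)),
    "F": lambda i, j: float(i * i + j * j),
    "GA": lambda i, j: 2.0 * math.sqrt(i * j) / (i + j),
    "H": lambda i, j: 2.0 / (i + j),
    "ISI": lambda i, j: (i * j) / (i + j),
    "M1": lambda i, j: float(i + j),
    "M2": lambda i, j: float(i * j),
    "S": lambda i, j: 1.0 / math.sqrt(i + j),
    "SO": lambda i, j: math.sqrt(i * i + j * j),
    "R": lambda i, j: 1.0 / math.sqrt(i * j),
}

#: Canonical order of the ten supported index names.
INDEX_NAMES: tuple[str, ...] = tuple(_WEIGHTS)


def entropy_column(name: str) -> str:
    """Column label for the entropy variant of an index (``Ent_ABC`` ...)."""
    return f"Ent_{name}"


def topological_column(name: str) -> str:
    return name


def edge_weight(name: str, i: int, j: int) -> float:
    """Edge weight phi(i, j) for the named index.

    Symmetric in (i, j) and strictly positive for all degrees >= 1,
    except ABC on a (1, 1) edge which returns 0 (flagged with a warning).
    """
    try:
        rule = _WEIGHTS[name]
    except KeyError:
        raise KeyError(
            f"unknown index name {name!r}; expected one of {', '.join(INDEX_NAMES)}"
        ) from None
    if not (i >= 1 and j >= 1):
        raise ValueError(f"degrees must be >= 1, got ({i}, {j})")
    w = rule(i, j)
    if w == 0.0:
        warnings.warn(
            f"{name} weight is 0 on a ({i},{j}) edge (degenerate K2 component); "
            "its entropy contribution is taken as 0",
            stacklevel=2,
        )
    return w


def topological_index(partition: EdgePartition, name: str) -> float:
    """Degree-based index T = sum over cells of n_ij * phi(i, j)."""
    return sum(n * edge_weight(name, i, j) for (i, j), n in partition.items())


def entropy_index(partition: EdgePartition, name: str) -> float:
    """Shannon-type entropy of the phi-weight distribution over edges.

    Equals -sum_e p_e ln p_e with p_e = phi_e / T; computed from the
    partition in O(#cells).  Natural logarithm.
    """
    total = 0.0
    weighted_log = 0.0
    for (i, j), n in partition.items():
        w = edge_weight(name, i, j)
        if w > 0.0:
            total += n * w
            weighted_log += n * w * math.log(w)
    if total <= 0.0:
        raise ValueError(
            f"entropy undefined for zero total weight ({name} on {dict(partition.items())})"
        )
    return math.log(total) - weighted_log / total


def descriptor_matrix(
    compounds: Sequence[tuple[str, EdgePartition]],
    names: Iterable[str] = INDEX_NAMES,
    kinds: str = "both",
) -> pd.DataFrame:
    """Per-compound table of entropy and/or topological index values.

    Parameters
    ----------
    compounds
        Sequence of (compound name, edge partition) pairs.
    names
        Index names to compute (any subset of :data:`INDEX_NAMES`).
    kinds
        ``"entropy"``, ``"topological"`` or ``"both"``.

    Values are kept at full floating precision; rounding to the 4
    decimal places conventional in the literature happens only when a
    table is serialized.
    """
    names = list(names)
    if not names:
        raise ValueError("empty index-name set")
    if not compounds:
        raise ValueError("no compounds supplied")
    unknown = [n for n in names if n not in _WEIGHTS]
    if unknown:
        raise KeyError(f"unknown index name(s): {unknown}")
    if kinds not in {"entropy", "topological", "both"}:
        raise ValueError(f"kinds must be entropy/topological/both, got {kinds!r}")

    rows = {}
    for label, part in compounds:
        row = {}
        try:
            if kinds in {"entropy", "both"}:
                for n in names:
                    row[entropy_column(n)] = entropy_index(part, n)
            if kinds in {"topological", "both"}:
                for n in names:
                    row[topological_column(n)] = topological_index(part, n)
        except ValueError as exc:
            raise ValueError(f"compound {label!r}: {exc}") from exc
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound"
    return df
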