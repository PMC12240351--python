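"""Chemistry-like random graphs and simulated property data.

The generator stands in for structure databases so every pipeline stage
is testable offline.  A synthetic "molecule" is a connected simple graph
grown as a degree-capped random tree (each new atom attaches to a
uniformly chosen atom that still has free valence) followed by random
ring closures between non-adjacent degree-deficient atom pairs.  With
the default degree cap of 4 the degree distribution resembles a
hydrogen-suppressed organic skeleton; no element or valence chemistry is
modelled.

Property data is simulated from a known curvilinear truth: for each
compound the chosen entropy descriptor h is computed and

    y = family(h; true coefficients) + Normal(0, sigma^2)

so parameter-recovery and CI-coverage behaviour of the regression stage
can be measured against ground truth.  Defaults mirror the study this
package reproduces: 14 compounds of 8-40 heavy atoms, cubic truth with
coefficients (a, b1, b2, b3) = (323.0, 18.4, -75.9, 24.7) on Ent_ABC,
and noise sd 40 (comparable to that study's cubic residual scale).

Reproducibility: a single integer seed drives one named stream per
dataset; per-compound substreams are derived by counter so compound
order is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .descriptors import INDEX_NAMES, descriptor_matrix
from .molgraph import MolecularGraph, edge_partition
from .qspr import FAMILIES, _K
from .validation import predict

__all__ = ["SyntheticSpec", "gen_graph", "gen_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset (identical spec => identical data)."""

    n_compounds: int = 14
    atom_range: tuple[int, int] = (8, 40)
    max_degree: int = 4
    ring_prob: float = 0.3
    descriptor: str = "Ent_ABC"
    family: str = "cubic"
    coefficients: tuple[float, ...] = (323.0, 18.4, -75.9, 24.7)
    noise_sd: float = 40.0
    property_name: str = "Y"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        lo, hi = self.atom_range
        if not (2 <= lo <= hi):
            raise ValueError("atom_range must satisfy 2 <= lo <= hi")
        if not (0.0 <= self.ring_prob <= 1.0):
            raise ValueError("ring_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        k = _K[self.family]
        if len(self.coefficients) != k + 1:
            raise ValueError(
                f"{self.family} truth needs {k + 1} coefficients (a, b1..b{k})"
            )
        if self.n_compounds < k + 2:
            raise ValueError(
                f"n_compounds={self.n_compounds} too small for a {self.family} truth "
                f"(need at least k + 2 = {k + 2})"
            )

    @property
    def true_model(self) -> dict:
        a, *b = self.coefficients
        b = (list(b) + [None, None, None])[:3]
        return {
            "family": self.family,
            "a": a,
            "b": tuple(b),
            "descriptor": self.descriptor,
            "property": self.property_name,
        }


def gen_graph(
    n_atoms: int,
    max_degree: int = 4,
    ring_prob: float = 0.3,
    seed: int | np.random.Generator = 0,
    name: str | None = None,
) -> MolecularGraph:
    """Random connected simple graph with all degrees in [1, max_degree].

    Grows a degree-capped random tree, then attempts ``n_atoms`` ring
    closures, each succeeding with probability ``ring_prob`` provided a
    non-adjacent pair with free valence exists.
    """
    if n_atoms < 1:
        raise ValueError("atom count must be >= 1")
    if n_atoms == 1:
        raise ValueError("a single isolated atom has no bonds; need >= 2 atoms")
    if max_degree < 2 and n_atoms > 2:
        raise ValueError("max_degree must be >= 2 for more than two atoms")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    g = nx.Graph()
    g.add_node("a0")
    for v in range(1, n_atoms):
        open_atoms = [u for u, d in g.degree() if d < max_degree]
        parent = open_atoms[rng.integers(len(open_atoms))]
        g.add_edge(parent, f"a{v}")

    for _ in range(n_atoms):
        if rng.random() >= ring_prob:
            continue
        deficient = [u for u, d in g.degree() if d < max_degree]
        if len(deficient) < 2:
            break
        # rejection-sample a non-adjacent pair with free valence
        for _attempt in range(16):
            ia, ib = rng.integers(len(deficient)), rng.integers(len(deficient))
            u, v = deficient[ia], deficient[ib]
            if u != v and not g.has_edge(u, v):
                g.add_edge(u, v)
                break

    return MolecularGraph(g, name=name)


def gen_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (descriptor table, property table, truth record).

    The descriptor table holds all ten entropy and ten topological
    columns; the property column is the chosen family evaluated at the
    chosen descriptor plus Gaussian noise.  The truth record stores the
    generating model, noise sd and per-compound noiseless values.
    """
    compounds = []
    noise = np.empty(spec.n_compounds)
    lo, hi = spec.atom_range
    for i in range(spec.n_compounds):
        sub = np.random.default_rng([spec.seed, i])
        n_atoms = int(sub.integers(lo, hi + 1))
        graph = gen_graph(
            n_atoms, spec.max_degree, spec.ring_prob, seed=sub, name=f"synth{i:03d}"
        )
        compounds.append((graph.name, edge_partition(graph)))
        noise[i] = sub.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0

    desc = descriptor_matrix(compounds, INDEX_NAMES, kinds="both")
    if spec.descriptor not in desc.columns:
        raise KeyError(f"unknown descriptor column {spec.descriptor!r}")
    h = desc[spec.descriptor].to_numpy()
    signal = np.array([predict(spec.true_model, v) for v in h])
    props = pd.DataFrame({spec.property_name: signal + noise}, index=desc.index)
    truth = {
        "model": spec.true_model,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "signal": signal.tolist(),
    }
    return desc, props, truth
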