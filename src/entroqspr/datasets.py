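"""Packaged reference data for the colorectal-cancer drug study.

The package ships, as plain-text fixtures, the published per-drug
entropy-descriptor table, the physicochemical property table, the
held-out (external validation) compounds Erbitux and Larotrectinib, the
Oxaliplatin edge partition, and the published best-fit cubic models.
Values are embedded exactly as printed in the source tables; two known
anomalies are retained verbatim (the Ent_GA entries for Carboplatin and
Fluorouracil exceed the ln m bound their molecules permit — evidently
data-entry slips) so the fixture is an honest transcription rather than
a silent correction.
"""

from __future__ import annotations

import io
import json
from importlib import resources

import pandas as pd

from .molgraph import EdgePartition, read_partition_csv
from .qspr import fit_from_dict

__all__ = [
    "load_drug_entropies",
    "load_drug_properties",
    "load_heldout_entropies",
    "load_heldout_properties",
    "oxaliplatin_partition",
    "published_models",
    "GA_ANOMALIES",
]

#: (compound, column) fixture cells known to be inconsistent with the
#: entropy bound 0 <= Ent <= ln m; kept verbatim, flagged here.
GA_ANOMALIES: tuple[tuple[str, str], ...] = (
    ("Carboplatin", "Ent_GA"),
    ("Fluorouracil", "Ent_GA"),
)


def _read_csv(name: str) -> pd.DataFrame:
    text = resources.files("entroqspr.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), index_col="compound")


def load_drug_entropies() -> pd.DataFrame:
    """Entropy-descriptor values of the 14 study drugs (10 columns)."""
    return _read_csv("drug_entropy_indices.csv")


def load_drug_properties() -> pd.DataFrame:
    """Physicochemical properties of the 14 study drugs.

    Columns: MW (molecular weight, g/mol), TSA (topological surface
    area), C (complexity), D (density), MV (molar volume),
    P (polarizability), MR (molar refractivity).
    """
    return _read_csv("drug_properties.csv")


def load_heldout_entropies() -> pd.DataFrame:
    """Entropy descriptors of the external-validation compounds."""
    return _read_csv("heldout_entropy_indices.csv")


def load_heldout_properties() -> pd.DataFrame:
    """Experimental properties of the external-validation compounds."""
    return _read_csv("heldout_properties.csv")


def oxaliplatin_partition() -> EdgePartition:
    """The published Oxaliplatin degree-pair edge partition (m = 17)."""
    text = resources.files("entroqspr.data").joinpath("oxaliplatin_partition.csv").read_text()
    return read_partition_csv(text, name="Oxaliplatin")


def published_models() -> list[dict]:
    """The published best-fit cubic models, as plain-coefficient records."""
    text = resources.files("entroqspr.data").joinpath("published_models.json").read_text()
    return [fit_from_dict(d) for d in json.loads(text)]
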