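"""Loaders for the bundled reference data.

The package ships, as plain-text data: the 18-state catalog with SNOMED CT
codings; the demographic composition of the 47-person study population; the
published per-state summary statistics of the SG and RS valuations; and the
prior North-American SG valuations of the same states (de Almeida et al.)
used as the external comparator.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import HealthState, load_state_catalog


def _data_path(name: str) -> Path:
    return Path(str(resources.files("utilicit").joinpath("data", name)))


def load_default_catalog() -> list[HealthState]:
    """The 18 valued health states with their SNOMED CT expressions."""
    return load_state_catalog(_data_path("states.json"))


def load_demographics() -> dict:
    """Study-population composition: category counts plus age distribution."""
    return json.loads(_data_path("demographics.json").read_text(encoding="utf-8"))


def load_reference_summary() -> pd.DataFrame:
    """Published per-state summary statistics (36 rows: 18 states × {SG, RS})."""
    return pd.read_csv(_data_path("reference_summary.csv"))


def load_comparator() -> pd.DataFrame:
    """Published comparator means and 95% CIs (NA where a state was not valued)."""
    return pd.read_csv(_data_path("comparator_dealmeida.csv"))


def scenario_text(scenario_ref: str) -> str:
    """Raw factsheet text for a scenario reference; content is opaque data."""
    path = _data_path(f"scenarios/{scenario_ref}.txt")
    return path.read_text(encoding="utf-8")
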