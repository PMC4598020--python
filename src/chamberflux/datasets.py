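"""Bundled reference datasets.

Small text tables shipped with the package:

* ``volume_trial_codes`` — consensus codes from a bench volume-ratio
  sensitivity trial on *Acropora* sp. (three replicate colonies per water
  volume, hourly sampling over 4 h, light and dark), ready for the volume
  acceptance rule;
* ``species_site_means`` — published hourly metabolic rates (mean ± SE,
  mmol m-2 h-1, n = 5) for three Brazilian reef corals at two lagoon
  sites, used as generating truth by the case-study simulator;
* ``water_extraction_trial`` — summary of 30 bench trials quantifying the
  chamber water left unrecovered by the syringe extraction procedure.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .volume import DecisionMatrix

__all__ = [
    "load_volume_trial_codes",
    "load_species_site_means",
    "load_water_extraction_trial",
    "read_decision_codes",
]


def _data_path(name: str):
    return resources.files("chamberflux.data").joinpath(name)


def read_decision_codes(path) -> DecisionMatrix:
    """Read a (volume, hour, phase, o2_code, dmet_code) table into a DecisionMatrix."""
    table = pd.read_csv(path, dtype={"o2_code": str, "dmet_code": str})
    return DecisionMatrix(table=table, meta={"source": str(path)})


def load_volume_trial_codes() -> DecisionMatrix:
    """Consensus codes of the bundled volume-ratio sensitivity trial."""
    with resources.as_file(_data_path("volume_trial_codes.csv")) as p:
        return read_decision_codes(p)


def load_species_site_means() -> pd.DataFrame:
    """Published species x site hourly rate means (mmol m-2 h-1) with SEs."""
    with resources.as_file(_data_path("species_site_means.csv")) as p:
        return pd.read_csv(p)


def load_water_extraction_trial() -> dict:
    """Summary of the bench water-extraction trials (volumes in ml)."""
    with resources.as_file(_data_path("water_extraction_trial.json")) as p:
        return json.loads(p.read_text(encoding="utf-8"))
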