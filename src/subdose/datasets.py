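"""Packaged study fixtures: the motivating paediatric trial data and defaults.

The motivating dataset is the single-agent paediatric dose-escalation trial
of Nicholson et al. (stratified by a pretreatment biomarker), which supplies
the dose grid {100, 150, 180, 215, 245, 260} mg/m^2, the adult recommended
dose 200 mg/m^2 as reference, and the observed DLT counts used to calibrate
the simulation scenarios.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import DoseGrid, EscalationPolicy, ToxicityDataset
from .prior import PriorDose, PseudoDataSpec

__all__ = [
    "default_grid",
    "default_policy",
    "nicholson_data",
    "default_pseudo_spec",
]


def _data_path(name: str):
    return resources.files("subdose.data").joinpath(name)


def default_grid() -> DoseGrid:
    """Dose set of the motivating trial with reference dose 200 mg/m^2."""
    return DoseGrid(doses=(100.0, 150.0, 180.0, 215.0, 245.0, 260.0), reference_dose=200.0)


def default_policy() -> EscalationPolicy:
    """Target TD16 with unacceptable toxicity level 0.35."""
    return EscalationPolicy(theta=0.16, delta=0.35)


def nicholson_data() -> ToxicityDataset:
    """Observed DLT counts from the motivating trial, by dose and subgroup."""
    with resources.as_file(_data_path("nicholson_dlt.csv")) as path:
        return ToxicityDataset.from_csv(path)


def default_pseudo_spec() -> PseudoDataSpec:
    """Default prior pseudo-data: per subgroup, 2 patients at 100 mg/m^2 with
    DLT proportion 1/6 and 1 patient at 260 mg/m^2 with proportion 1/2
    (3 pseudo-patients per subgroup = 1/10th of the planned 30).  The pooled
    prior used by the homogeneous-population design is more pessimistic at
    the top dose: 4 patients at 100 with proportion 1/6 and 2 patients at
    260 with proportion 1."""
    with resources.as_file(_data_path("default_prior.csv")) as path:
        frame = pd.read_csv(path)
    by_scope: dict[str, list[PriorDose]] = {"negative": [], "positive": [], "pooled": []}
    for row in frame.itertuples(index=False):
        by_scope[str(row.scope)].append(
            PriorDose(
                dose=float(row.dose),
                dlt_proportion=float(row.dlt_proportion),
                patient_weight=float(row.patient_weight),
            )
        )
    return PseudoDataSpec(
        negative=tuple(by_scope["negative"]),
        positive=tuple(by_scope["positive"]),
        pooled=tuple(by_scope["pooled"]) or None,
    )
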