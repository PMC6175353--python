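"""Pseudo-data priors and the slab component derived from them.

Prior opinion about toxicity is encoded as *pseudo-data*: for each subgroup,
a prior proportion of DLTs at two prior doses, weighted to a fraction
(conventionally 1/10th) of the planned subgroup sample size.  Fitting the
pseudo-data alongside trial data makes the MAP estimate a weighted MLE, and
fitting the pseudo-data alone yields both the advised starting dose and the
normal "slab" used by the spike-and-slab variable-selection prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    FULL,
    POOLED,
    DoseGrid,
    DoseToxicityFit,
    EscalationPolicy,
    ToxicityDataset,
    ToxicityRecord,
    fit_model,
    select_dose,
)

__all__ = [
    "PriorDose",
    "PseudoDataSpec",
    "SlabPrior",
    "expand_pseudo_data",
    "derive_slab",
    "prior_advised_start_dose",
]


@dataclass(frozen=True)
class PriorDose:
    """One prior dose: proportion of DLTs and pseudo-patient weight."""

    dose: float
    dlt_proportion: float
    patient_weight: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dlt_proportion <= 1.0):
            raise ValueError("prior DLT proportion must lie in [0, 1]")
        if self.patient_weight <= 0:
            raise ValueError("prior patient weight must be positive")


@dataclass(frozen=True)
class PseudoDataSpec:
    """Prior doses per subgroup (two each by design convention), plus an
    optional distinct pooled row used by the homogeneous-population design.

    The pooled prior may be more pessimistic than the aggregate of the
    per-subgroup rows (a boundary DLT proportion of 1 at the top dose is
    allowed); when absent, the pooled view is the union of the per-subgroup
    rows."""

    negative: tuple[PriorDose, PriorDose]
    positive: tuple[PriorDose, PriorDose]
    pooled: Optional[tuple[PriorDose, ...]] = None

    def per_subgroup(self, g: int) -> tuple[PriorDose, ...]:
        return self.positive if g == 1 else self.negative

    def total_weight(self, g: int) -> float:
        return sum(p.patient_weight for p in self.per_subgroup(g))


@dataclass(frozen=True)
class SlabPrior:
    """Normal slab over (b0, b1, b2, b3) plus prior inclusion weights.

    ``mean`` and ``cov`` come from the four-parameter fit to the pseudo-data
    alone; the sampler uses the independent components ``N(mean_j, cov_jj)``,
    matching the usual independent spike-and-slab formulation.  Inclusion
    weights for b0 and b1 are identically 1.
    """

    mean: np.ndarray
    cov: np.ndarray
    spike_weights: tuple[float, float, float, float] = (1.0, 1.0, 0.5, 0.5)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if mean.shape != (4,) or cov.shape != (4, 4):
            raise ValueError("slab prior must cover all four coefficients")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("slab covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("slab covariance must be positive definite")
        w = self.spike_weights
        if any(not (0.0 <= wj <= 1.0) for wj in w):
            raise ValueError("inclusion weights must lie in [0, 1]")
        if w[0] != 1.0 or w[1] != 1.0:
            raise ValueError("b0 and b1 are always included (weight 1)")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def expand_pseudo_data(spec: PseudoDataSpec, pooled: bool = False) -> ToxicityDataset:
    """Expand prior doses into fractional-weight toxicity records.

    A prior dose with proportion ``p`` and weight ``n`` becomes a record with
    ``n*p`` DLTs and ``n*(1-p)`` non-DLTs, flagged as pseudo-data.  With
    ``pooled=True`` the pooled prior rows are expanded instead (used by the
    homogeneous-population design; subgroup labels are immaterial there and
    set to 0).
    """
    data = ToxicityDataset()
    if pooled and spec.pooled is not None:
        for pd_ in spec.pooled:
            data.add(
                ToxicityRecord(
                    dose=pd_.dose,
                    subgroup=0,
                    dlt_weight=pd_.patient_weight * pd_.dlt_proportion,
                    no_dlt_weight=pd_.patient_weight * (1.0 - pd_.dlt_proportion),
                    is_pseudo=True,
                )
            )
        return data
    for g in (0, 1):
        for pd_ in spec.per_subgroup(g):
            data.add(
                ToxicityRecord(
                    dose=pd_.dose,
                    subgroup=g,
                    dlt_weight=pd_.patient_weight * pd_.dlt_proportion,
                    no_dlt_weight=pd_.patient_weight * (1.0 - pd_.dlt_proportion),
                    is_pseudo=True,
                )
            )
    return data


def derive_slab(
    pseudo: ToxicityDataset,
    grid: DoseGrid,
    slab_scale: float = 1.0,
    prior_inclusion: tuple[float, float] = (0.5, 0.5),
) -> SlabPrior:
    """Slab component from the four-parameter fit to the pseudo-data alone.

    The slab mean is the coefficient estimate and the slab covariance is
    ``slab_scale`` times the inverse observed information of that fit, so the
    prior's strength stays tied to the pseudo-data weight.  Boundary DLT
    proportions (0 or 1) or too few support points leave the fit
    non-identifiable and raise.
    """
    if slab_scale <= 0:
        raise ValueError("slab_scale must be positive")
    fit = fit_model(pseudo.pseudo_only(), FULL, grid)
    if not fit.converged or fit.vcov is None:
        raise ValueError(
            "pseudo-data does not identify the four-parameter model: "
            + (fit.message or "fit failed")
        )
    return SlabPrior(
        mean=fit.beta_full,
        cov=slab_scale * fit.vcov,
        spike_weights=(1.0, 1.0, float(prior_inclusion[0]), float(prior_inclusion[1])),
    )


def prior_advised_start_dose(
    pseudo: ToxicityDataset,
    grid: DoseGrid,
    policy: EscalationPolicy,
) -> Optional[float]:
    """Dose the escalation rule advises from the pseudo-data alone.

    The pooled two-parameter model is fitted to the pseudo-data only and the
    gain-maximising safe dose over the full grid is returned (``None`` if the
    prior already rules every dose unsafe).
    """
    fit = fit_model(pseudo.pseudo_only(), POOLED, grid)
    if not fit.converged:
        raise ValueError("pseudo-data prior fit failed: " + fit.message)
    return select_dose(fit, grid, policy, subgroup=0)
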