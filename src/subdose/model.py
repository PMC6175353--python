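"""Dose-toxicity modelling for subgroup-aware dose-escalation.

The dose-toxicity relationship is modelled on the logit scale as a linear
function of the standardised dose ``log(x/d* + 1)``, where ``d*`` is a fixed
reference dose.  For a population split into biomarker-negative (``g = 0``)
and biomarker-positive (``g = 1``) subgroups the four-parameter logistic
model is

    logit pi(x, g) = b0 + b1 * log(x/d* + 1) + g * (b2 + b3 * log(x/d* + 1))

so that ``b2`` and ``b3`` carry an intercept and slope shift for the positive
subgroup.  Dropping both subgroup terms recovers the homogeneous-population
two-parameter model.

Prior knowledge enters as *pseudo-data*: fractional patients with DLT
outcomes at two prior doses, fitted alongside real observations.  The modal
a-posteriori estimate under such a prior equals the maximum-likelihood
estimate on the augmented data, so a single weighted-binomial Newton fit
serves both purposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "DoseGrid",
    "ToxicityRecord",
    "ToxicityDataset",
    "ModelSpec",
    "DoseToxicityFit",
    "EscalationPolicy",
    "standardise_dose",
    "predict_prob",
    "fit_model",
    "td_estimate",
    "td_interval",
    "select_dose",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DoseGrid:
    """Ordered discrete dose set with the reference dose used to standardise.

    Parameters
    ----------
    doses
        Strictly increasing dose levels (mg/m^2), all positive.
    reference_dose
        Positive reference dose ``d*``; the standardised dose is
        ``log(x/d* + 1)``, zero at ``x = 0`` and increasing in ``x``.
    """

    doses: tuple[float, ...]
    reference_dose: float

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        if len(doses) == 0:
            raise ValueError("dose grid must be nonempty")
        if any(d <= 0 for d in doses):
            raise ValueError("all doses must be positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.reference_dose <= 0:
            raise ValueError("reference dose must be positive")

    def standardise(self, x) -> np.ndarray | float:
        return standardise_dose(x, self)


def standardise_dose(x, grid: DoseGrid):
    """``log(x/d* + 1)`` for dose ``x >= 0`` (scalar or array)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("dose must be nonnegative")
    out = np.log(arr / grid.reference_dose + 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ToxicityRecord:
    """One weighted binomial observation (possibly a fractional pseudo-patient)."""

    dose: float
    subgroup: int
    dlt_weight: float
    no_dlt_weight: float
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.subgroup not in (0, 1):
            raise ValueError("subgroup indicator must be 0 or 1")
        if self.dlt_weight < 0 or self.no_dlt_weight < 0:
            raise ValueError("weights must be nonnegative")
        if self.dlt_weight + self.no_dlt_weight <= 0:
            raise ValueError("record must carry positive total weight")


@dataclass
class ToxicityDataset:
    """Collection of weighted DLT / no-DLT records, pseudo and observed.

    Fractional weights are permitted; prior pseudo-patients are flagged with
    ``is_pseudo`` so the trial-data-only view used for final recommendations
    can be recovered with :meth:`trial_only`.
    """

    records: list[ToxicityRecord] = field(default_factory=list)

    _CSV_COLUMNS = ("dose", "subgroup", "dlt_weight", "no_dlt_weight", "is_pseudo")

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: ToxicityRecord) -> None:
        self.records.append(record)

    def extend(self, records: Iterable[ToxicityRecord]) -> None:
        self.records.extend(records)

    def trial_only(self) -> "ToxicityDataset":
        return ToxicityDataset([r for r in self.records if not r.is_pseudo])

    def pseudo_only(self) -> "ToxicityDataset":
        return ToxicityDataset([r for r in self.records if r.is_pseudo])

    def subgroup(self, g: int) -> "ToxicityDataset":
        return ToxicityDataset([r for r in self.records if r.subgroup == g])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(dose, subgroup, dlt_weight, no_dlt_weight) as float arrays."""
        if not self.records:
            return (np.empty(0),) * 4
        dose = np.array([r.dose for r in self.records], dtype=float)
        g = np.array([r.subgroup for r in self.records], dtype=float)
        y1 = np.array([r.dlt_weight for r in self.records], dtype=float)
        y0 = np.array([r.no_dlt_weight for r in self.records], dtype=float)
        return dose, g, y1, y0

    def total_patients(self, subgroup: Optional[int] = None) -> float:
        recs = self.records if subgroup is None else self.subgroup(subgroup).records
        return sum(r.dlt_weight + r.no_dlt_weight for r in recs)

    def total_dlts(self, subgroup: Optional[int] = None) -> float:
        recs = self.records if subgroup is None else self.subgroup(subgroup).records
        return sum(r.dlt_weight for r in recs)

    # -- CSV round trip ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.dose, r.subgroup, r.dlt_weight, r.no_dlt_weight, r.is_pseudo)
                for r in self.records
            ],
            columns=list(self._CSV_COLUMNS),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ToxicityDataset":
        missing = [c for c in cls._CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        records = [
            ToxicityRecord(
                dose=float(row.dose),
                subgroup=int(row.subgroup),
                dlt_weight=float(row.dlt_weight),
                no_dlt_weight=float(row.no_dlt_weight),
                is_pseudo=bool(row.is_pseudo),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records)

    @classmethod
    def from_csv(cls, path) -> "ToxicityDataset":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty or malformed CSV: {path}") from exc
        return cls.from_frame(frame)


@dataclass(frozen=True)
class ModelSpec:
    """Which subgroup terms enter the model; b0 and b1 are always included."""

    include_beta2: bool = False
    include_beta3: bool = False

    @property
    def n_params(self) -> int:
        return 2 + int(self.include_beta2) + int(self.include_beta3)

    @property
    def columns(self) -> tuple[int, ...]:
        """Indices into the full (b0, b1, b2, b3) coefficient vector."""
        cols = [0, 1]
        if self.include_beta2:
            cols.append(2)
        if self.include_beta3:
            cols.append(3)
        return tuple(cols)

    @property
    def uses_subgroup(self) -> bool:
        return self.include_beta2 or self.include_beta3


POOLED = ModelSpec(False, False)
FULL = ModelSpec(True, True)


@dataclass(frozen=True)
class EscalationPolicy:
    """Target DLT probability ``theta`` and unacceptable level ``delta``.

    A dose is administrable only while its estimated DLT probability is below
    ``delta``; among those, the dose maximising the patient gain
    ``1/(pi_hat - theta)^2`` (equivalently minimising ``|pi_hat - theta|``)
    is chosen.
    """

    theta: float = 0.16
    delta: float = 0.35

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < self.delta < 1.0):
            raise ValueError("require 0 < theta < delta < 1")


@dataclass(frozen=True)
class DoseToxicityFit:
    """Fitted coefficients of the (possibly reduced) logistic model.

    ``beta`` always has length 4 on the (b0, b1, b2, b3) layout; coefficients
    excluded by ``spec`` are pinned at zero.  ``vcov`` is the inverse observed
    information over the *included* coefficients (``spec.columns`` order).
    """

    beta: tuple[float, float, float, float]
    spec: ModelSpec
    grid: DoseGrid
    converged: bool
    vcov: Optional[np.ndarray] = None
    message: str = ""

    @property
    def beta_full(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    def linear_predictor(self, x, subgroup: int) -> np.ndarray | float:
        z = standardise_dose(x, self.grid)
        b = self.beta_full
        eta = b[0] + b[1] * np.asarray(z)
        if subgroup == 1:
            eta = eta + b[2] + b[3] * np.asarray(z)
        return eta

    def intercept_slope(self, subgroup: int) -> tuple[float, float]:
        """Effective (intercept, slope) on the standardised-dose scale."""
        b = self.beta_full
        if subgroup == 1:
            return float(b[0] + b[2]), float(b[1] + b[3])
        return float(b[0]), float(b[1])


def predict_prob(fit: DoseToxicityFit, x, subgroup: int):
    """Fitted DLT probability at dose ``x`` for the given subgroup."""
    eta = fit.linear_predictor(x, subgroup)
    p = expit(eta)
    return float(p) if np.ndim(p) == 0 else p


# ---------------------------------------------------------------------------
# fitting


def _design(z: np.ndarray, g: np.ndarray, spec: ModelSpec) -> np.ndarray:
    full = np.column_stack([np.ones_like(z), z, g, g * z])
    return full[:, list(spec.columns)]


def _loglik(X: np.ndarray, y1: np.ndarray, n: np.ndarray, b: np.ndarray) -> float:
    eta = X @ b
    return float(np.sum(y1 * eta - n * np.logaddexp(0.0, eta)))


def fit_model(
    data: ToxicityDataset,
    spec: ModelSpec,
    grid: DoseGrid,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DoseToxicityFit:
    """Weighted-binomial maximum-likelihood fit by Newton with step-halving.

    With pseudo-data included the result is the MAP estimate under the
    pseudo-data prior.  Convergence is declared when the relative
    log-likelihood change drops below ``tol`` (the standard GLM deviance
    criterion; on quasi-separated data the printed estimates depend on this
    tolerance, and the default matches common GLM software).  Rank-deficient
    designs (too few support points for the requested terms) and fits whose
    information matrix cannot be inverted are flagged via ``converged=False``
    rather than returning silent garbage; quasi-separation is noted in
    ``message``.
    """
    dose, g, y1, y0 = data.arrays()
    if dose.size == 0:
        return DoseToxicityFit(
            (0.0, 0.0, 0.0, 0.0), spec, grid, False, None, "empty dataset"
        )
    z = standardise_dose(dose, grid)
    X = _design(np.atleast_1d(z), g, spec)
    n = y1 + y0
    k = spec.n_params

    support = {(float(d), int(gg)) for d, gg in zip(dose, g)}
    Xs = _design(
        np.array([standardise_dose(d, grid) for d, _ in support]),
        np.array([gg for _, gg in support], dtype=float),
        spec,
    )
    if np.linalg.matrix_rank(Xs) < k:
        return DoseToxicityFit(
            (0.0, 0.0, 0.0, 0.0), spec, grid, False, None,
            "non-identifiable: design rank below number of free parameters",
        )

    b = np.zeros(k)
    if spec.uses_subgroup:
        # warm start at the pooled fit: keeps the Newton path away from the
        # saturated region when subgroup cells are sparse
        pooled = fit_model(data, POOLED, grid, max_iter=max_iter, tol=tol)
        if pooled.converged:
            b[0], b[1] = pooled.beta_full[0], pooled.beta_full[1]
    ll = _loglik(X, y1, n, b)
    converged = False
    message = "maximum iterations reached"
    for _ in range(max_iter):
        p = expit(X @ b)
        grad = X.T @ (y1 - n * p)
        w = n * p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving line search on the log-likelihood
        t = 1.0
        ll_new = -np.inf
        for _ in range(50):
            b_new = b + t * step
            ll_new = _loglik(X, y1, n, b_new)
            if ll_new >= ll - 1e-14:
                break
            t *= 0.5
        if abs(ll_new - ll) < tol * (abs(ll_new) + 1.0):
            b, ll = b_new, ll_new
            converged = True
            message = ""
            break
        b, ll = b_new, ll_new

    if converged and float(np.max(np.abs(X @ b))) > 30.0:
        message = "quasi-separated: estimates at the convergence tolerance"

    vcov = None
    if converged:
        p = expit(X @ b)
        H = X.T @ (X * (n * p * (1.0 - p))[:, None])
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            converged = False
            message = "singular observed information at optimum"

    beta_full = np.zeros(4)
    beta_full[list(spec.columns)] = b
    return DoseToxicityFit(tuple(beta_full), spec, grid, converged, vcov, message)


# ---------------------------------------------------------------------------
# dose recommendation


def td_estimate(fit: DoseToxicityFit, theta: float, subgroup: int = 0) -> float:
    """Continuous TD100theta: the dose with fitted DLT probability ``theta``.

    Analytic inversion of the logit: ``x = d* (exp[(logit(theta) - a)/b] - 1)``
    for effective intercept ``a`` and slope ``b``.
    """
    a, b = fit.intercept_slope(subgroup)
    if b <= 0:
        raise ValueError("effective slope must be positive for a TD estimate")
    return float(fit.grid.reference_dose * (math.exp((logit(theta) - a) / b) - 1.0))


def td_interval(
    fit: DoseToxicityFit, theta: float, subgroup: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Delta-method normal interval for TD100theta on the dose (mg/m^2) scale.

    Uses the observed-information covariance of the fit.  Raises if the fit
    carries no covariance or the effective slope is non-positive.
    """
    from scipy.stats import norm

    if fit.vcov is None:
        raise ValueError("fit carries no covariance matrix")
    a, b = fit.intercept_slope(subgroup)
    if b <= 0:
        raise ValueError("effective slope must be positive")
    u = (logit(theta) - a) / b
    td = fit.grid.reference_dose * (math.exp(u) - 1.0)
    # gradient wrt (a, b), mapped onto the included coefficients
    dda = fit.grid.reference_dose * math.exp(u) * (-1.0 / b)
    ddb = fit.grid.reference_dose * math.exp(u) * (-u / b)
    grad = []
    for col in fit.spec.columns:
        if col == 0:
            grad.append(dda)
        elif col == 1:
            grad.append(ddb)
        elif col == 2:
            grad.append(dda if subgroup == 1 else 0.0)
        else:
            grad.append(ddb if subgroup == 1 else 0.0)
    grad = np.asarray(grad)
    var = float(grad @ fit.vcov @ grad)
    if var < 0:
        raise ValueError("negative delta-method variance")
    half = norm.ppf(0.5 + level / 2.0) * math.sqrt(var)
    return (td - half, td + half)


def select_dose(
    fit: DoseToxicityFit,
    grid: DoseGrid,
    policy: EscalationPolicy,
    subgroup: int = 0,
    allowed: Optional[Sequence[float]] = None,
) -> Optional[float]:
    """Gain-maximising safe dose, or ``None`` when no allowed dose is safe.

    Among allowed doses with ``pi_hat < delta`` the dose maximising the
    patient gain ``1/(pi_hat - theta)^2`` is returned.  Selection is
    implemented as ``argmin |pi_hat - theta|`` (the same ordering, with no
    division by zero at an exact hit); ties break to the lower dose.
    ``None`` signals the safety stop.
    """
    doses = np.asarray(grid.doses if allowed is None else sorted(allowed), dtype=float)
    if allowed is not None and not set(np.round(doses, 9)) <= set(
        np.round(grid.doses, 9)
    ):
        raise ValueError("allowed doses must be a subset of the grid")
    if doses.size == 0:
        return None
    p = predict_prob(fit, doses, subgroup)
    p = np.atleast_1d(p)
    safe = p < policy.delta
    if not np.any(safe):
        return None
    idx = np.where(safe)[0]
    best = idx[int(np.argmin(np.abs(p[idx] - policy.theta)))]  # first = lowest dose
    return float(doses[best])
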