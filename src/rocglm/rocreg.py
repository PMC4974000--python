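"""Covariate-adjusted probit ROC regression (ROC-GLM).

The model is a binormal ROC curve whose intercept shifts with covariates of
the diseased subjects:

    ROC(q | x) = Phi( alpha1 + alpha2 * Phi^-1(q) + beta' x )

where q is the false-positive rate, Phi the standard normal CDF and x a
covariate profile (here: visual field index, age, spherical equivalent,
axial length, corrected optic disc area).  The covariate-specific area under
the curve has the closed form

    AUC(x) = Phi( (alpha1 + beta' x) / sqrt(1 + alpha2^2) ).

Estimation follows the placement-value / binary-indicator construction of
Alonzo & Pepe: each case's marker value is converted to its survival
percentile in the pooled control sample (its placement value), the indicator
``u_ij = 1{pv_i <= q_j}`` is expanded over a grid of false-positive rates,
and u is regressed on ``[1, Phi^-1(q_j), x_i]`` by maximum-likelihood
probit.  Indicators within a case are correlated, so the model-based
standard errors are not valid; inference is by stratified bootstrap over
cases and controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._probit import FitConvergenceError, ProbitResult, QuasiSeparationWarning, fit_probit
from ._rng import substream

__all__ = [
    "Direction",
    "MarkerSpec",
    "FprGrid",
    "PlacementValues",
    "RocCoefficients",
    "RocGlmFit",
    "CoefficientSummary",
    "BootstrapResult",
    "orient_marker",
    "placement_values",
    "expand_indicators",
    "fit",
    "roc_at",
    "auc",
    "auc_numeric",
    "auc_table",
    "bootstrap",
    "STUDY_COVARIATES",
    "study_profile",
]

#: Covariates of the five-covariate study model, in reporting order.
STUDY_COVARIATES = (
    "vfi",
    "age",
    "spherical_equivalent",
    "axial_length",
    "corrected_disc_area",
)


def study_profile(
    vfi: float,
    age: float = 55.0,
    spherical_equivalent: float = -2.15,
    axial_length: float = 24.5,
    corrected_disc_area: float = 2.0,
) -> dict[str, float]:
    """Covariate profile in the study's units; defaults are the reporting
    baseline (age 55 y, SE -2.15 D, AL 24.5 mm, corrected disc area 2 mm^2)."""
    return {
        "vfi": vfi,
        "age": age,
        "spherical_equivalent": spherical_equivalent,
        "axial_length": axial_length,
        "corrected_disc_area": corrected_disc_area,
    }


class Direction(str, Enum):
    LOWER_IS_DISEASED = "lower_is_diseased"
    HIGHER_IS_DISEASED = "higher_is_diseased"


@dataclass(frozen=True)
class MarkerSpec:
    """A diagnostic marker and its disease direction.

    OCT thickness markers thin with glaucomatous loss, so they default to
    ``lower_is_diseased``.
    """

    name: str
    direction: Direction = Direction.LOWER_IS_DISEASED

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class FprGrid:
    """Strictly increasing false-positive rates in the open interval (0, 1)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise ValueError("FPR grid needs at least two points")
        if np.any(v <= 0.0) or np.any(v >= 1.0):
            raise ValueError("FPR grid values must lie strictly inside (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("FPR grid must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def uniform(cls, m: int = 100) -> "FprGrid":
        """Midpoint grid q_j = (2j-1)/(2m), j=1..m; avoids the probit poles."""
        j = np.arange(1, m + 1)
        return cls(tuple((2 * j - 1) / (2 * m)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def orient_marker(values, spec: MarkerSpec) -> np.ndarray:
    """Orient marker values so that larger means more diseased."""
    v = np.asarray(values, dtype=float)
    return -v if spec.direction is Direction.LOWER_IS_DISEASED else v.copy()


@dataclass(frozen=True)
class PlacementValues:
    """Cases' marker values as survival percentiles of the control sample."""

    values: np.ndarray
    n_controls: int
    tie_rule: str

    def __len__(self) -> int:
        return len(self.values)


def placement_values(
    case_values,
    control_values,
    *,
    tie_rule: str = "inclusive",
) -> PlacementValues:
    """Placement value of each case against the pooled control distribution.

    ``pv_i = #{controls >= case_i} / n_controls`` (inclusive rule, default:
    a control tied with the case counts as at least as diseased).  The
    ``strict`` rule counts only controls strictly greater.  Inputs must be
    oriented (larger = more diseased); pv near 0 means the case looks more
    diseased than every control.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if controls.size == 0:
        raise ValueError("placement values need a non-empty control sample")
    if tie_rule not in ("inclusive", "strict"):
        raise ValueError(f"unknown tie rule: {tie_rule!r}")
    ctrl = np.sort(controls)
    # inclusive: count controls >= case  -> n - searchsorted(left)
    # strict:    count controls >  case  -> n - searchsorted(right)
    side = "left" if tie_rule == "inclusive" else "right"
    count_ge = controls.size - np.searchsorted(ctrl, cases, side=side)
    return PlacementValues(
        values=count_ge / controls.size,
        n_controls=int(controls.size),
        tie_rule=tie_rule,
    )


def expand_indicators(
    pv: PlacementValues,
    grid: FprGrid,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format indicator table for the probit working regression.

    One row per (case, grid point): ``u = 1{pv_i <= q_j}``, ``probit_q =
    Phi^-1(q_j)``, plus the case's covariates repeated across its grid rows.
    """
    n = len(pv)
    q = grid.as_array()
    m = q.size
    if covariates is not None and len(covariates) != n:
        raise ValueError(
            f"covariate rows ({len(covariates)}) must match cases ({n})"
        )
    u = (pv.values[:, None] <= q[None, :]).astype(float)
    out = pd.DataFrame(
        {
            "case_index": np.repeat(np.arange(n), m),
            "q": np.tile(q, n),
            "probit_q": np.tile(ndtri(q), n),
            "u": u.ravel(),
        }
    )
    if covariates is not None:
        for col in covariates.columns:
            out[col] = np.repeat(np.asarray(covariates[col], dtype=float), m)
    return out


@dataclass(frozen=True)
class RocCoefficients:
    """Parameters of the covariate-adjusted binormal ROC curve."""

    alpha1: float
    alpha2: float
    betas: Mapping[str, float] = field(default_factory=dict)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.betas)

    def linear_shift(self, profile: Mapping[str, float]) -> float:
        """alpha1 + beta' x for a covariate profile."""
        missing = [k for k in self.betas if k not in profile]
        if missing:
            raise ValueError(f"profile missing covariate(s): {missing}")
        return float(self.alpha1 + sum(b * float(profile[k]) for k, b in self.betas.items()))


@dataclass
class RocGlmFit:
    """Fitted ROC regression.

    ``naive_cov`` is the inverse Fisher information of the working probit
    likelihood; it ignores the within-case correlation of the indicators and
    is therefore NOT valid for inference — use :func:`bootstrap`.
    """

    coefficients: RocCoefficients
    marker: MarkerSpec
    grid: FprGrid
    tie_rule: str
    n_cases: int
    n_controls: int
    converged: bool
    n_iter: int
    separation: bool
    naive_cov: np.ndarray
    bootstrap_draws: np.ndarray | None = None  # (B, 2+k) resampled coefficient vectors

    @property
    def alpha1(self) -> float:
        return self.coefficients.alpha1

    @property
    def alpha2(self) -> float:
        return self.coefficients.alpha2

    @property
    def betas(self) -> Mapping[str, float]:
        return self.coefficients.betas

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return self.coefficients.covariate_names

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("alpha1", "alpha2") + self.covariate_names

    def params(self) -> np.ndarray:
        return np.array(
            [self.alpha1, self.alpha2] + [self.betas[k] for k in self.covariate_names]
        )


def _coerce_coefficients(fit_or_coeffs) -> RocCoefficients:
    if isinstance(fit_or_coeffs, RocGlmFit):
        return fit_or_coeffs.coefficients
    if isinstance(fit_or_coeffs, RocCoefficients):
        return fit_or_coeffs
    raise TypeError(f"expected RocGlmFit or RocCoefficients, got {type(fit_or_coeffs)!r}")


def _fit_core(
    oriented_cases: np.ndarray,
    oriented_controls: np.ndarray,
    cov_mat: np.ndarray | None,
    q: np.ndarray,
    probit_q: np.ndarray,
    tie_rule: str,
) -> ProbitResult:
    """Numpy-only estimation path shared by :func:`fit` and :func:`bootstrap`.

    Equivalent to ``placement_values`` -> ``expand_indicators`` -> probit,
    without the DataFrame round trip (the bootstrap refits this thousands of
    times).
    """
    n, m = oriented_cases.size, q.size
    side = "left" if tie_rule == "inclusive" else "right"
    ctrl = np.sort(oriented_controls)
    pv = (ctrl.size - np.searchsorted(ctrl, oriented_cases, side=side)) / ctrl.size
    u = (pv[:, None] <= q[None, :]).ravel().astype(float)
    k = 0 if cov_mat is None else cov_mat.shape[1]
    X = np.empty((n * m, 2 + k))
    X[:, 0] = 1.0
    X[:, 1] = np.tile(probit_q, n)
    if cov_mat is not None:
        X[:, 2:] = np.repeat(cov_mat, m, axis=0)
    return fit_probit(X, u)


def fit(
    case_values,
    control_values,
    case_covariates: pd.DataFrame | None,
    spec: MarkerSpec,
    grid: FprGrid | None = None,
    *,
    tie_rule: str = "inclusive",
) -> RocGlmFit:
    """Fit the covariate-adjusted ROC regression.

    Parameters
    ----------
    case_values, control_values : raw marker measurements per group.
    case_covariates : one row per case with the covariate columns that enter
        the ROC linear predictor (controls contribute only through the
        placement-value reference distribution); ``None`` fits a
        covariate-free binormal ROC.
    spec : marker name and disease direction.
    grid : false-positive-rate grid; defaults to 100 uniform midpoints.

    Raises :class:`rocglm._probit.FitConvergenceError` on non-convergence;
    warns (not fails) on quasi-separation or degenerate indicators.
    """
    grid = grid or FprGrid.uniform()
    cases = orient_marker(case_values, spec)
    controls = orient_marker(control_values, spec)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both case and control samples must be non-empty")
    names = tuple(case_covariates.columns) if case_covariates is not None else ()
    if tie_rule not in ("inclusive", "strict"):
        raise ValueError(f"unknown tie rule: {tie_rule!r}")

    q = grid.as_array()
    cov_mat = (
        np.asarray(case_covariates, dtype=float) if case_covariates is not None else None
    )
    res = _fit_core(cases, controls, cov_mat, q, ndtri(q), tie_rule)

    coeffs = RocCoefficients(
        alpha1=float(res.params[0]),
        alpha2=float(res.params[1]),
        betas={k: float(v) for k, v in zip(names, res.params[2:])},
    )
    if coeffs.alpha2 <= 0 and not res.separation:
        warnings.warn(
            f"fitted alpha2={coeffs.alpha2:.4f} <= 0: not a proper binormal "
            "ROC slope; check marker direction",
            stacklevel=2,
        )
    return RocGlmFit(
        coefficients=coeffs,
        marker=spec,
        grid=grid,
        tie_rule=tie_rule,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
        converged=res.converged,
        n_iter=res.n_iter,
        separation=res.separation,
        naive_cov=res.cov,
    )


def roc_at(fit_or_coeffs, profile: Mapping[str, float] | None, q):
    """Covariate-specific ROC curve: sensitivity at false-positive rate q.

    ``q`` may be a scalar or array; every value must lie strictly in (0, 1).
    """
    coeffs = _coerce_coefficients(fit_or_coeffs)
    qa = np.asarray(q, dtype=float)
    if np.any(qa <= 0.0) or np.any(qa >= 1.0):
        raise ValueError("false-positive rate must lie strictly in (0, 1)")
    shift = coeffs.linear_shift(profile or {})
    out = ndtr(shift + coeffs.alpha2 * ndtri(qa))
    return float(out) if out.ndim == 0 else out


def auc(fit_or_coeffs, profile: Mapping[str, float] | None = None) -> float:
    """Covariate-specific AUROC, closed form Phi((alpha1+beta'x)/sqrt(1+alpha2^2))."""
    coeffs = _coerce_coefficients(fit_or_coeffs)
    if coeffs.alpha2 <= 0:
        raise ValueError(f"invalid fit: alpha2={coeffs.alpha2!r} must be positive")
    shift = coeffs.linear_shift(profile or {})
    return float(ndtr(shift / np.sqrt(1.0 + coeffs.alpha2**2)))


def auc_numeric(fit_or_coeffs, profile: Mapping[str, float] | None = None, n_nodes: int = 256) -> float:
    """AUROC by Gauss–Legendre quadrature of the ROC curve over (0, 1).

    Independent numerical check of the closed form; used by the tests.
    """
    if n_nodes < 64:
        raise ValueError("use at least 64 quadrature nodes")
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    q = 0.5 * (nodes + 1.0)  # map [-1,1] -> (0,1)
    vals = roc_at(fit_or_coeffs, profile, q)
    return float(0.5 * np.sum(weights * vals))


def auc_table(fit_or_coeffs, profiles: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """One closed-form AUROC per covariate profile, as a tidy table."""
    rows = []
    for prof in profiles:
        rows.append({**{k: float(v) for k, v in prof.items()}, "auc": auc(fit_or_coeffs, prof)})
    cols = (list(profiles[0].keys()) + ["auc"]) if len(profiles) else ["auc"]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class CoefficientSummary:
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "bootstrap_percentile"


@dataclass
class BootstrapResult:
    summaries: tuple[CoefficientSummary, ...]
    draws: np.ndarray           # (B_ok, n_params)
    n_requested: int
    n_failed: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "coefficient": s.name,
                    "estimate": s.estimate,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "p_value": s.p_value,
                    "method": s.method,
                }
                for s in self.summaries
            ]
        )


def bootstrap(
    case_values,
    control_values,
    case_covariates: pd.DataFrame | None,
    spec: MarkerSpec,
    grid: FprGrid | None = None,
    *,
    B: int = 1000,
    seed: int,
    tie_rule: str = "inclusive",
    max_failure_fraction: float = 0.10,
) -> BootstrapResult:
    """Stratified bootstrap inference for the ROC regression coefficients.

    Cases (with their covariate rows) and controls are resampled with
    replacement separately; the model is refitted per replicate.  Reported
    per coefficient: the full-sample estimate, percentile 95% CI, and a
    two-sided p-value from a normal approximation with the bootstrap SE.
    Replicates that fail to converge are dropped; more than
    ``max_failure_fraction`` of them is an error.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    grid = grid or FprGrid.uniform()
    full = fit(case_values, control_values, case_covariates, spec, grid, tie_rule=tie_rule)
    cases = orient_marker(case_values, spec)
    controls = orient_marker(control_values, spec)
    cov_mat = (
        np.asarray(case_covariates, dtype=float) if case_covariates is not None else None
    )
    q = grid.as_array()
    zq = ndtri(q)

    rng = substream(seed, "bootstrap")
    draws = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QuasiSeparationWarning)
        for _ in range(B):
            ci = rng.integers(0, cases.size, cases.size)
            oi = rng.integers(0, controls.size, controls.size)
            try:
                rep = _fit_core(
                    cases[ci],
                    controls[oi],
                    cov_mat[ci] if cov_mat is not None else None,
                    q,
                    zq,
                    tie_rule,
                )
            except (FitConvergenceError, np.linalg.LinAlgError):
                n_failed += 1
                continue
            if rep.separation:
                n_failed += 1
                continue
            draws.append(rep.params)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge"
        )
    draw_mat = np.asarray(draws)

    estimates = full.params()
    lo, hi = np.percentile(draw_mat, [2.5, 97.5], axis=0)
    se = draw_mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, estimates / se, np.inf)
    p = 2.0 * norm.sf(np.abs(z))
    summaries = tuple(
        CoefficientSummary(
            name=name,
            estimate=float(estimates[i]),
            ci_low=float(lo[i]),
            ci_high=float(hi[i]),
            p_value=float(p[i]),
            method="bootstrap_percentile",
        )
        for i, name in enumerate(full.param_names)
    )
    full.bootstrap_draws = draw_mat
    return BootstrapResult(
        summaries=summaries,
        draws=draw_mat,
        n_requested=B,
        n_failed=n_failed,
        seed=seed,
    )
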