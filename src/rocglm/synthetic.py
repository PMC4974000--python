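"""Synthetic case-control cohorts with a known covariate-specific ROC.

The generator exploits the binormal identity: if the oriented marker
(larger = more diseased) is Normal(mu0, sigma0^2) in controls and, given a
case's covariates x, Normal(mu0 + (sigma0/alpha2) * (alpha1 + beta'x),
(sigma0/alpha2)^2) in cases, then the true covariate-specific ROC is exactly

    ROC(q | x) = Phi( alpha1 + alpha2 * Phi^-1(q) + beta' x ),

i.e. the estimand of :mod:`rocglm.rocreg` with the chosen coefficients as
ground truth.  Covariates are drawn as independent truncated normals whose
per-group means/SDs default to the published characteristics of the
motivating cohort (173 glaucomatous / 63 control eyes); truncation (VFI at
100%, positive thicknesses and areas) is enforced by rejection so requested
group sizes are never silently reduced.  All remaining record fields
(quality indices, acuity, IOP, cylinder) are filled with eligibility-passing
values so a generated cohort survives the exclusion filter intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .cohort import Cohort, cohort_from_frame, covariate_frame
from .magnification import DEFAULT_CONSTANTS, bennett_corrected_area
from .rocreg import Direction, FprGrid, MarkerSpec, bootstrap, fit

__all__ = [
    "TruncatedNormal",
    "CovariateDistribution",
    "SyntheticTruth",
    "study_covariate_distributions",
    "study_truth",
    "generate",
    "recovery_study",
]


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd^2) restricted to (lower, upper) by rejection."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.lower >= self.upper:
            raise ValueError("empty truncation interval")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = rng.normal(self.mean, self.sd, n)
        bad = (out < self.lower) | (out > self.upper)
        # rejection refill keeps the requested sample size exact
        while bad.any():
            out[bad] = rng.normal(self.mean, self.sd, int(bad.sum()))
            bad = (out < self.lower) | (out > self.upper)
        return out


@dataclass(frozen=True)
class CovariateDistribution:
    """Per-covariate, per-group marginal distributions.

    ``specs[covariate][group]`` is a :class:`TruncatedNormal`;
    groups are "glaucoma" and "control".
    """

    specs: Mapping[str, Mapping[str, TruncatedNormal]]

    def sample(self, rng: np.random.Generator, group: str, n: int) -> pd.DataFrame:
        return pd.DataFrame(
            {name: by_group[group].sample(rng, n) for name, by_group in self.specs.items()}
        )


def study_covariate_distributions() -> CovariateDistribution:
    """Marginals matching the published per-group means (SDs).

    Covariate units: age years, spherical equivalent diopters, axial length
    mm, disc area mm^2 (instrument scale), VFI percent (truncated at 100;
    the control mean of 99.27 forces the upper truncation), visual-field
    global indices dB.
    """
    g, c = "glaucoma", "control"
    return CovariateDistribution(
        {
            "age": {g: TruncatedNormal(55.16, 11.28, 18.0, 95.0),
                    c: TruncatedNormal(53.71, 11.73, 18.0, 95.0)},
            "spherical_equivalent": {g: TruncatedNormal(-2.28, 3.14),
                                     c: TruncatedNormal(-1.78, 3.69)},
            "axial_length": {g: TruncatedNormal(24.69, 1.48, 20.0, 30.0),
                             c: TruncatedNormal(24.12, 1.58, 20.0, 30.0)},
            "disc_area_measured": {g: TruncatedNormal(1.95, 0.41, 0.5, 4.5),
                                   c: TruncatedNormal(2.07, 0.43, 0.5, 4.5)},
            "vfi": {g: TruncatedNormal(88.99, 9.85, 0.0, 100.0),
                    c: TruncatedNormal(99.27, 1.08, 0.0, 100.0)},
            "md": {g: TruncatedNormal(-4.19, 3.45, -33.0, 3.0),
                   c: TruncatedNormal(-0.47, 1.53, -33.0, 3.0)},
            "psd": {g: TruncatedNormal(6.74, 4.12, 0.2, 18.0),
                    c: TruncatedNormal(1.85, 0.52, 0.2, 18.0)},
            "bcva_logmar": {g: TruncatedNormal(0.07, 0.12, 0.0, 0.30),
                            c: TruncatedNormal(0.06, 0.11, 0.0, 0.30)},
            "iop": {g: TruncatedNormal(13.08, 2.45, 6.0, 21.0),
                    c: TruncatedNormal(13.23, 2.19, 6.0, 21.0)},
        }
    )


#: Control-group marker means (SDs) on the raw thickness scale (um).
_CONTROL_MARKERS = {
    "rnfl_avg": (93.05, 8.80),
    "gcipl_avg": (79.21, 11.68),
    "gcipl_min": (76.81, 6.83),
}
#: Case-group marginals used for the *incidental* markers (those not driven
#: by the truth model) so every thickness column is populated.
_CASE_MARKERS = {
    "rnfl_avg": (76.95, 10.49),
    "gcipl_avg": (71.66, 7.58),
    "gcipl_min": (60.45, 11.25),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth ROC-GLM coefficients and marker model for the generator."""

    alpha1: float
    alpha2: float
    betas: Mapping[str, float]
    marker: str = "rnfl_avg"
    direction: Direction = Direction.LOWER_IS_DISEASED
    control_mean: float = _CONTROL_MARKERS["rnfl_avg"][0]   # mu0, raw scale
    control_sd: float = _CONTROL_MARKERS["rnfl_avg"][1]     # sigma0
    n_cases: int = 173
    n_controls: int = 63

    def __post_init__(self) -> None:
        if self.alpha2 <= 0:
            raise ValueError("alpha2 must be positive (proper binormal ROC)")
        if self.control_sd <= 0:
            raise ValueError("control marker SD must be positive")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("both group sizes must be at least 1")
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "betas", dict(self.betas))

    @property
    def case_sd(self) -> float:
        """sigma_D = sigma0 / alpha2 of the oriented case marker."""
        return self.control_sd / self.alpha2


def study_truth(marker: str, alpha1: float, alpha2: float, betas: Mapping[str, float],
                n_cases: int = 173, n_controls: int = 63) -> SyntheticTruth:
    """Truth with the named marker's published control mean/SD."""
    mu, sd = _CONTROL_MARKERS[marker]
    return SyntheticTruth(
        alpha1=alpha1, alpha2=alpha2, betas=betas, marker=marker,
        control_mean=mu, control_sd=sd, n_cases=n_cases, n_controls=n_controls,
    )


def _oriented_sign(direction: Direction) -> float:
    return -1.0 if direction is Direction.LOWER_IS_DISEASED else 1.0


def generate(
    truth: SyntheticTruth,
    dists: CovariateDistribution | None = None,
    *,
    seed: int,
) -> Cohort:
    """Generate a cohort whose true covariate-specific ROC is the truth model.

    The covariates named in ``truth.betas`` must be generated ones (any of
    the distribution's columns plus ``corrected_disc_area``, which is
    derived from measured area and axial length by the Bennett correction).
    Only cases' covariates shift the marker; the control marker is drawn
    covariate-free, mirroring the pooled-reference fitting convention.
    """
    dists = dists or study_covariate_distributions()
    rng_cov = substream(seed, "synthetic-covariates")
    rng_marker = substream(seed, "synthetic-marker")
    rng_aux = substream(seed, "synthetic-auxiliary")

    frames = {}
    for group, n in (("glaucoma", truth.n_cases), ("control", truth.n_controls)):
        df = dists.sample(rng_cov, group, n)
        df["corrected_disc_area"] = bennett_corrected_area(
            df["disc_area_measured"].to_numpy(),
            df["axial_length"].to_numpy(),
            DEFAULT_CONSTANTS,
        )
        df["disc_area_corrected"] = df["corrected_disc_area"]
        frames[group] = df

    unknown = [k for k in truth.betas if k not in frames["glaucoma"].columns]
    if unknown:
        raise ValueError(f"truth references ungenerated covariate(s): {unknown}")

    sign = _oriented_sign(truth.direction)
    mu0_oriented = sign * truth.control_mean
    sigma_d = truth.case_sd

    x = frames["glaucoma"][list(truth.betas)].to_numpy(dtype=float)
    b = np.array([truth.betas[k] for k in truth.betas])
    shift = (truth.control_sd / truth.alpha2) * (truth.alpha1 + x @ b)
    case_oriented = rng_marker.normal(mu0_oriented + shift, sigma_d)
    control_oriented = rng_marker.normal(mu0_oriented, truth.control_sd, truth.n_controls)

    rows = []
    sid = 0
    for group, oriented in (("glaucoma", case_oriented), ("control", control_oriented)):
        df = frames[group].copy()
        n = len(df)
        df["subject_id"] = [f"S{(sid + i):04d}" for i in range(n)]
        sid += n
        df["eye"] = rng_aux.choice(["right", "left"], n)
        df["group"] = group
        df["sex"] = rng_aux.choice(["female", "male"], n)
        df[truth.marker] = sign * oriented
        for other, (mu_g, sd_g) in _CASE_MARKERS.items():
            if other == truth.marker:
                continue
            mu, sd = (mu_g, sd_g) if group == "glaucoma" else _CONTROL_MARKERS[other]
            df[other] = TruncatedNormal(mu, sd, 1.0).sample(rng_aux, n)
        # eligibility-passing quality fields
        df["cylinder"] = np.clip(rng_aux.normal(-0.5, 0.8, n), -2.9, 2.9)
        df["signal_strength_macula"] = rng_aux.integers(6, 11, n).astype(float)
        df["signal_strength_disc"] = rng_aux.integers(6, 11, n).astype(float)
        df["vf_fixation_loss"] = rng_aux.uniform(0.0, 15.0, n)
        df["vf_false_positive"] = rng_aux.uniform(0.0, 20.0, n)
        rows.append(df)
    frame = pd.concat(rows, ignore_index=True)

    # a thickness marker at or below zero is outside the record's domain;
    # with realistic truths this is a many-sigma event, but guard anyway
    bad = frame[truth.marker] <= 0
    if bad.any():
        frame.loc[bad, truth.marker] = 0.1

    return cohort_from_frame(frame, provenance=f"synthetic(seed={seed})")


def recovery_study(
    truth: SyntheticTruth,
    dists: CovariateDistribution | None = None,
    *,
    n_replicates: int = 100,
    seed: int,
    grid: FprGrid | None = None,
    bootstrap_B: int = 0,
    max_failure_fraction: float = 0.10,
) -> pd.DataFrame:
    """Replicate generate -> fit (-> bootstrap) and summarise estimator error.

    Returns one row per coefficient with columns: truth, mean_estimate,
    bias, mc_se (Monte-Carlo SE of the mean estimate), rmse and — when
    ``bootstrap_B`` > 0 — the empirical coverage of the percentile 95% CI.
    Replicates whose fit fails are counted and skipped; more than
    ``max_failure_fraction`` failing is an error.
    """
    if n_replicates < 50:
        raise ValueError("use at least 50 replicates")
    dists = dists or study_covariate_distributions()
    grid = grid or FprGrid.uniform()
    spec = MarkerSpec(truth.marker, truth.direction)
    names = ("alpha1", "alpha2") + tuple(truth.betas)
    true_vec = np.array([truth.alpha1, truth.alpha2, *truth.betas.values()])

    master = substream(seed, "recovery-study")
    estimates = []
    covered = []
    n_failed = 0
    for _ in range(n_replicates):
        rep_seed = int(master.integers(2**31))
        cohort = generate(truth, dists, seed=rep_seed)
        f = cohort.frame
        cases = f.loc[f["group"] == "glaucoma", truth.marker].to_numpy()
        controls = f.loc[f["group"] == "control", truth.marker].to_numpy()
        cov = covariate_frame(f.loc[f["group"] == "glaucoma"], truth.betas)
        try:
            if bootstrap_B > 0:
                res = bootstrap(
                    cases, controls, cov, spec, grid,
                    B=bootstrap_B, seed=rep_seed,
                )
                est = np.array([s.estimate for s in res.summaries])
                covered.append(
                    [
                        s.ci_low <= t <= s.ci_high
                        for s, t in zip(res.summaries, true_vec)
                    ]
                )
            else:
                rep_fit = fit(cases, controls, cov, spec, grid)
                est = rep_fit.params()
        except Exception:
            n_failed += 1
            continue
        estimates.append(est)

    if n_failed > max_failure_fraction * n_replicates:
        raise RuntimeError(f"{n_failed}/{n_replicates} replicate fits failed")
    est = np.asarray(estimates)
    out = pd.DataFrame(
        {
            "coefficient": names,
            "truth": true_vec,
            "mean_estimate": est.mean(axis=0),
            "bias": est.mean(axis=0) - true_vec,
            "mc_se": est.std(axis=0, ddof=1) / math.sqrt(len(est)),
            "rmse": np.sqrt(((est - true_vec) ** 2).mean(axis=0)),
        }
    )
    if covered:
        out["coverage"] = np.asarray(covered, dtype=float).mean(axis=0)
    out.attrs["n_replicates"] = len(est)
    out.attrs["n_failed"] = n_failed
    return out
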