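"""End-to-end analysis pipeline.

Composes the full study analysis — ingest (or simulate), eligibility
exclusions, one-eye-per-subject selection, magnification correction,
characteristics table, per-marker covariate-adjusted ROC fits with bootstrap
inference, and covariate-specific AUROC grids / ROC point sets — under one
config with a manifest that fully determines the outputs.

Also provides the desk-scale path: evaluating the published regression
coefficients over the published covariate profiles, with no fitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream_seed
from .cohort import (
    Cohort,
    ExclusionCriteria,
    apply_exclusions,
    covariate_frame,
    read_cohort,
    select_one_eye_per_subject,
    write_cohort,
)
from .descriptive import table1_frame
from .magnification import correct_disc_area
from .rocreg import (
    Direction,
    FprGrid,
    MarkerSpec,
    RocCoefficients,
    auc,
    auc_table,
    bootstrap,
    fit,
    roc_at,
    study_profile,
)
from . import synthetic

__all__ = [
    "PipelineConfig",
    "load_reference_coefficients",
    "reference_coefficient_sets",
    "reproduce_reference_tables",
    "run",
]

log = logging.getLogger(__name__)

#: Marker display order used in every output table.
MARKERS = ("rnfl_avg", "gcipl_avg", "gcipl_min")


def load_reference_coefficients() -> dict:
    """Packaged published coefficient sets and evaluation profiles."""
    with resources.files("rocglm.data").joinpath("reference_coefficients.json").open() as fh:
        return json.load(fh)


def reference_coefficient_sets() -> dict[str, RocCoefficients]:
    raw = load_reference_coefficients()
    return {
        name: RocCoefficients(m["alpha1"], m["alpha2"], dict(m["betas"]))
        for name, m in raw["markers"].items()
    }


def reproduce_reference_tables(
    coefficient_sets: Mapping[str, RocCoefficients] | None = None,
) -> dict[str, pd.DataFrame]:
    """Covariate-specific AUROC grids from (published or fitted) coefficients.

    Returns three tables, all via the closed form, no fitting involved:

    * ``auc_by_severity`` — VFI 100/90/80/70 at the baseline profile (age 55,
      SE -2.15 D, AL 24.5 mm, corrected disc area 2 mm^2), one column per
      marker;
    * ``auc_by_axial_length`` — AL 23/24.5/26 mm at VFI 92%, average RNFL and
      average GCIPL;
    * ``auc_by_disc_area`` — corrected disc area 1.5/2/2.5 mm^2 at VFI 92%,
      average RNFL.
    """
    raw = load_reference_coefficients()
    sets = coefficient_sets or reference_coefficient_sets()
    base = raw["baseline_profile"]
    vfi_geom = raw["geometry_series_vfi"]

    sev = pd.DataFrame({"vfi": raw["severity_grid_vfi"]})
    for m in MARKERS:
        if m in sets:
            sev[m] = [
                auc(sets[m], study_profile(v, **base)) for v in sev["vfi"]
            ]

    al = pd.DataFrame({"axial_length": raw["axial_length_grid"]})
    for m in ("rnfl_avg", "gcipl_avg"):
        if m in sets:
            al[m] = [
                auc(sets[m], {**study_profile(vfi_geom, **base), "axial_length": a})
                for a in al["axial_length"]
            ]

    coda = pd.DataFrame({"corrected_disc_area": raw["disc_area_grid"]})
    if "rnfl_avg" in sets:
        coda["rnfl_avg"] = [
            auc(sets["rnfl_avg"], {**study_profile(vfi_geom, **base), "corrected_disc_area": c})
            for c in coda["corrected_disc_area"]
        ]

    return {"auc_by_severity": sev, "auc_by_axial_length": al, "auc_by_disc_area": coda}


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    output_dir: str | Path = "rocglm_output"
    input_path: str | Path | None = None          # delimited cohort table, or None
    schema: dict[str, str] = field(default_factory=dict)
    delimiter: str = ","
    synthetic_marker: str = "gcipl_avg"           # truth marker when simulating
    n_cases: int = 173
    n_controls: int = 63
    exclusions: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    markers: dict[str, str] = field(
        default_factory=lambda: {m: "lower_is_diseased" for m in MARKERS}
    )
    covariates: tuple[str, ...] = (
        "vfi", "age", "spherical_equivalent", "axial_length", "corrected_disc_area"
    )
    grid_size: int = 100
    bootstrap_B: int = 1000
    seed: int = 0
    roc_curve_points: int = 99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exclusions" in raw:
            raw["exclusions"] = ExclusionCriteria(**raw["exclusions"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for m, d in self.markers.items():
            Direction(d)
            if m not in MARKERS and self.input_path is None:
                raise ValueError(
                    f"unknown marker {m!r}: synthetic cohorts provide {MARKERS}"
                )
        bad = [c for c in self.covariates if c not in (
            "vfi", "age", "spherical_equivalent", "axial_length",
            "corrected_disc_area", "md", "psd", "disc_area_measured",
        )]
        if bad:
            raise ValueError(f"unknown covariate(s): {bad}")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")


def _config_digest(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(config.__dict__, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path, config.schema, delimiter=config.delimiter)
    refs = load_reference_coefficients()["markers"][config.synthetic_marker]
    truth = synthetic.study_truth(
        config.synthetic_marker,
        refs["alpha1"],
        refs["alpha2"],
        refs["betas"],
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )
    return synthetic.generate(
        truth, seed=substream_seed(config.seed, "pipeline-simulate")
    )


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Output bundle (all delimited text / JSON under ``config.output_dir``):
    retained cohort, exclusion report, characteristics table, per-marker
    coefficient tables with bootstrap CIs, covariate-specific AUROC grids,
    ROC curve point sets, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        cohort = _load_or_simulate(config)
        log.info("ingest: %d records (%s)", len(cohort), cohort.provenance)

        stage = "exclusions"
        cohort, report = apply_exclusions(cohort, config.exclusions)
        (out / "exclusion_report.json").write_text(report.to_json())

        stage = "eye-selection"
        cohort = select_one_eye_per_subject(cohort, config.seed)

        stage = "magnification"
        cohort = correct_disc_area(cohort)
        write_cohort(cohort, out / "analysis_cohort.csv")

        stage = "table1"
        t1 = table1_frame(cohort)
        t1.to_csv(out / "table1.csv", index=False)

        stage = "roc-regression"
        cohort.require_both_groups()
        frame = cohort.frame
        grid = FprGrid.uniform(config.grid_size)
        is_case = frame["group"] == "glaucoma"
        warnings_seen: list[str] = []
        fitted = {}
        all_cov = covariate_frame(frame, config.covariates)
        for marker, direction in config.markers.items():
            spec = MarkerSpec(marker, Direction(direction))
            keep = frame[marker].notna() & all_cov.notna().all(axis=1)
            cases = frame.loc[is_case & keep, marker].to_numpy()
            controls = frame.loc[~is_case & keep, marker].to_numpy()
            cov = all_cov.loc[is_case & keep].reset_index(drop=True)
            boot = bootstrap(
                cases, controls, cov, spec, grid,
                B=config.bootstrap_B,
                seed=substream_seed(config.seed, f"bootstrap-{marker}"),
            )
            marker_fit = fit(cases, controls, cov, spec, grid)
            if marker_fit.separation:
                warnings_seen.append(f"{marker}: quasi-separation in working probit")
            fitted[marker] = marker_fit
            boot.as_frame().to_csv(out / f"coefficients_{marker}.csv", index=False)

        stage = "auc-grids"
        sets = {m: f.coefficients for m, f in fitted.items()}
        tables = reproduce_reference_tables(sets)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)

        stage = "roc-curves"
        raw = load_reference_coefficients()
        base = raw["baseline_profile"]
        qs = FprGrid.uniform(config.roc_curve_points).as_array()
        curves = []
        for m, coeffs in sets.items():
            for vfi in raw["severity_grid_vfi"]:
                sens = roc_at(coeffs, study_profile(vfi, **base), qs)
                curves.append(
                    pd.DataFrame({"marker": m, "vfi": vfi, "fpr": qs, "sensitivity": sens})
                )
        pd.concat(curves, ignore_index=True).to_csv(out / "roc_curves.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": _config_digest(config),
        "n_input": report.n_input,
        "n_retained_after_exclusions": report.n_retained,
        "n_analysis": len(cohort),
        "group_sizes": cohort.group_sizes(),
        "markers": {
            m: {
                "coefficients": {
                    k: v for k, v in zip(fitted[m].param_names, fitted[m].params())
                },
                "converged": fitted[m].converged,
            }
            for m in fitted
        },
        "warnings": warnings_seen,
        "outputs": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
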