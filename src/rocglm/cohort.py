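"""Eye-level cohort I/O, validation, eligibility filtering and eye selection.

A cohort is one row per eye of a case-control study of glaucoma diagnostics:
demographics, refraction, axial length, Humphrey visual-field global indices,
OCT thickness markers and scan/field quality indicators.  This module reads
delimited text into a typed :class:`Cohort`, enforces the study eligibility
rules (visual acuity, IOP, cylinder, OCT signal strength), and reduces the
table to one randomly chosen eye per subject.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "EyeRecord",
    "Cohort",
    "ExclusionCriteria",
    "ExclusionReport",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "cohort_from_frame",
    "write_cohort",
    "apply_exclusions",
    "select_one_eye_per_subject",
]

#: Columns that must be present and parseable in any input table.
MANDATORY_COLUMNS = ("subject_id", "eye", "group")

#: Numeric columns with their validity ranges (closed unless noted).
_RANGES: dict[str, tuple[float, float]] = {
    "vfi": (0.0, 100.0),
    "signal_strength_macula": (0.0, 10.0),
    "signal_strength_disc": (0.0, 10.0),
    "vf_fixation_loss": (0.0, 100.0),
    "vf_false_positive": (0.0, 100.0),
}

#: Bennett nodal-point offset: axial lengths at or below this are outside the
#: magnification model's domain.
_AL_LOWER = 1.82

_POSITIVE_COLUMNS = ("rnfl_avg", "gcipl_avg", "gcipl_min", "disc_area_measured")

GROUPS = ("glaucoma", "control")

#: Model covariates whose conventional name differs from the record field
#: that stores them (the ROC model speaks of "corrected optic disc area").
COVARIATE_ALIASES = {"corrected_disc_area": "disc_area_corrected"}


def covariate_frame(frame: pd.DataFrame, names: Iterable[str]) -> pd.DataFrame:
    """Select model-covariate columns from a cohort frame.

    Accepts either record field names or their model aliases; output columns
    carry the requested names.
    """
    out = {}
    for name in names:
        col = name if name in frame.columns else COVARIATE_ALIASES.get(name)
        if col is None or col not in frame.columns:
            raise KeyError(f"unknown covariate: {name!r}")
        out[name] = frame[col].to_numpy(dtype=float)
    return pd.DataFrame(out)


class SchemaError(ValueError):
    """A mandatory column is absent from the input table."""


class CohortValidationError(ValueError):
    """One or more cells violate a declared range/domain invariant."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "cohort validation failed:\n  " + "\n  ".join(problems)
        )


@dataclass
class EyeRecord:
    """One eye's demographic, ocular, visual-field and OCT measurements."""

    subject_id: str
    eye: str                      # "left" / "right"
    group: str                    # "glaucoma" / "control"
    age: float = np.nan           # years
    sex: str = ""                 # "female" / "male"
    bcva_logmar: float = np.nan   # best-corrected visual acuity, logMAR
    iop: float = np.nan           # intraocular pressure, mmHg
    spherical_equivalent: float = np.nan   # diopters
    cylinder: float = np.nan      # diopters
    axial_length: float = np.nan  # mm
    md: float = np.nan            # visual-field mean deviation, dB
    psd: float = np.nan           # pattern standard deviation, dB
    vfi: float = np.nan           # visual field index, percent
    disc_area_measured: float = np.nan     # mm^2, instrument scale
    disc_area_corrected: float = np.nan    # mm^2, magnification-corrected
    rnfl_avg: float = np.nan      # average peripapillary RNFL thickness, um
    gcipl_avg: float = np.nan     # average macular GCIPL thickness, um
    gcipl_min: float = np.nan     # minimum macular GCIPL thickness, um
    signal_strength_macula: float = np.nan  # 0-10
    signal_strength_disc: float = np.nan    # 0-10
    vf_fixation_loss: float = np.nan        # percent
    vf_false_positive: float = np.nan       # percent


#: All recognised column names, in canonical order.
COLUMNS = tuple(f.name for f in dc_fields(EyeRecord))

_STRING_COLUMNS = ("subject_id", "eye", "group", "sex")


def _validate_frame(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    for col, (lo, hi) in _RANGES.items():
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        for idx in df.index[bad]:
            problems.append(
                f"row {idx}: {col}={df.at[idx, col]!r} outside [{lo}, {hi}]"
            )
    if "axial_length" in df.columns:
        vals = df["axial_length"]
        bad = vals.notna() & (vals <= _AL_LOWER)
        for idx in df.index[bad]:
            problems.append(
                f"row {idx}: axial_length={df.at[idx, 'axial_length']!r} "
                f"must exceed {_AL_LOWER} mm"
            )
    for col in _POSITIVE_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & (vals <= 0)
        for idx in df.index[bad]:
            problems.append(
                f"row {idx}: {col}={df.at[idx, col]!r} must be positive"
            )
    bad_group = ~df["group"].isin(GROUPS)
    for idx in df.index[bad_group]:
        problems.append(
            f"row {idx}: group={df.at[idx, 'group']!r} not one of {GROUPS}"
        )
    dup = df.duplicated(subset=["subject_id", "eye"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["subject_id", "eye"]].drop_duplicates()
        for _, row in keys.iterrows():
            problems.append(
                f"duplicate record for subject_id={row.subject_id!r} "
                f"eye={row.eye!r}"
            )
    return problems


@dataclass
class Cohort:
    """Ordered collection of eye records backed by a DataFrame.

    Rows keep their input order through every filter so downstream seeded
    operations are reproducible.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        for col in COLUMNS:
            if col not in self.frame.columns:
                self.frame[col] = "" if col in _STRING_COLUMNS else np.nan
        self.frame = self.frame[list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[EyeRecord]:
        for _, row in self.frame.iterrows():
            yield EyeRecord(**{c: row[c] for c in COLUMNS})

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.frame["group"] == g).sum()) for g in GROUPS}

    def require_both_groups(self) -> None:
        sizes = self.group_sizes()
        empty = [g for g, n in sizes.items() if n == 0]
        if empty:
            raise ValueError(f"cohort has no records in group(s): {empty}")

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "Cohort":
        return Cohort(
            self.frame.loc[mask].copy(),
            provenance=provenance if provenance is not None else self.provenance,
        )


@dataclass
class ExclusionReport:
    """Audit trail for eligibility filtering: every removal names its rule."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (subject, eye, rule)
    n_input: int = 0
    n_retained: int = 0

    @property
    def counts_per_rule(self) -> dict[str, int]:
        return dict(Counter(rule for _, _, rule in self.entries))

    @property
    def n_excluded(self) -> int:
        return len({(s, e) for s, e, _ in self.entries})

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "n_excluded": self.n_excluded,
                "counts_per_rule": self.counts_per_rule,
                "entries": [
                    {"subject_id": s, "eye": e, "rule": r}
                    for s, e, r in self.entries
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class ExclusionCriteria:
    """Eligibility thresholds.

    Defaults encode the study rules: best-corrected acuity worse than 20/40
    (0.30 logMAR), IOP exceeding 21 mmHg, cylinder outside +/-3 D, and any
    OCT signal strength below 6.  All bounds are exclusive in the direction
    the rule names ("exceeding 21" keeps 21).
    """

    bcva_logmar_max: float = 0.30
    iop_max: float = 21.0
    cylinder_min: float = -3.0
    cylinder_max: float = 3.0
    signal_strength_min: float = 6.0
    #: slack so 20/40 eyes recorded as exactly 0.30 logMAR are retained
    bcva_tolerance: float = 1e-9


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
    provenance: str | None = None,
) -> Cohort:
    """Read a delimited eye-level table into a validated :class:`Cohort`.

    Parameters
    ----------
    path : file with a header row.
    schema : optional mapping of canonical field name -> file column name;
        unmapped canonical names are looked up verbatim.
    delimiter : field separator (comma default).

    Raises
    ------
    SchemaError if a mandatory column is missing, ValueError on an empty
    file, CohortValidationError listing every offending row/field if any
    cell violates a range invariant.  Unparseable numeric cells are reported,
    never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.empty:
        raise ValueError(f"empty cohort file: {path}")

    rename = {}
    for canonical, source in (schema or {}).items():
        if canonical not in COLUMNS:
            raise SchemaError(f"unknown canonical field in schema: {canonical!r}")
        if source not in df.columns:
            raise SchemaError(f"schema maps {canonical!r} to absent column {source!r}")
        rename[source] = canonical
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    problems: list[str] = []
    out = pd.DataFrame(index=df.index)
    for col in COLUMNS:
        if col in _STRING_COLUMNS:
            out[col] = df[col].astype(str).str.strip() if col in df.columns else ""
            continue
        if col not in df.columns:
            out[col] = np.nan
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].astype(str).str.strip() != "") & parsed.isna()
        for idx in df.index[bad]:
            problems.append(f"row {idx}: {col}={df.at[idx, col]!r} is not numeric")
        out[col] = parsed

    problems.extend(_validate_frame(out))
    if problems:
        raise CohortValidationError(problems)
    return Cohort(out, provenance=provenance or str(path))


def cohort_from_frame(df: pd.DataFrame, provenance: str = "") -> Cohort:
    """Wrap an in-memory DataFrame as a Cohort, enforcing the invariants."""
    problems = _validate_frame(df)
    if problems:
        raise CohortValidationError(problems)
    return Cohort(df.copy(), provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path, *, delimiter: str = ",") -> None:
    cohort.frame.to_csv(path, sep=delimiter, index=False)


def _rule_mask(frame: pd.DataFrame, criteria: ExclusionCriteria) -> list[tuple[str, pd.Series]]:
    """(rule name, boolean mask of violators); NaN never violates."""
    c = criteria
    return [
        (
            f"bcva worse than 20/40 (logMAR > {c.bcva_logmar_max:g})",
            frame["bcva_logmar"] > c.bcva_logmar_max + c.bcva_tolerance,
        ),
        (f"IOP exceeding {c.iop_max:g} mmHg", frame["iop"] > c.iop_max),
        (
            f"cylinder outside [{c.cylinder_min:g}, {c.cylinder_max:g}] D",
            (frame["cylinder"] < c.cylinder_min) | (frame["cylinder"] > c.cylinder_max),
        ),
        (
            f"signal strength < {c.signal_strength_min:g}",
            (frame["signal_strength_macula"] < c.signal_strength_min)
            | (frame["signal_strength_disc"] < c.signal_strength_min),
        ),
    ]


def apply_exclusions(
    cohort: Cohort,
    criteria: ExclusionCriteria | None = None,
) -> tuple[Cohort, ExclusionReport]:
    """Filter a cohort by the eligibility rules.

    Returns the retained cohort (input order preserved) plus a report in
    which every excluded eye appears with each rule it violated.  Missing
    values in an optional field never trigger exclusion; they are warned
    about once per field.
    """
    criteria = criteria or ExclusionCriteria()
    frame = cohort.frame
    report = ExclusionReport(n_input=len(frame))

    for col in ("bcva_logmar", "iop", "cylinder",
                "signal_strength_macula", "signal_strength_disc"):
        n_missing = int(frame[col].isna().sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} record(s) missing {col}; eligibility rule not "
                "applied to them",
                stacklevel=2,
            )

    excluded = pd.Series(False, index=frame.index)
    for rule, mask in _rule_mask(frame, criteria):
        mask = mask.fillna(False)
        excluded |= mask
        for idx in frame.index[mask]:
            report.entries.append(
                (str(frame.at[idx, "subject_id"]), str(frame.at[idx, "eye"]), rule)
            )

    retained = cohort.subset(~excluded)
    report.n_retained = len(retained)
    if len(retained) == 0:
        warnings.warn("all records excluded; retained cohort is empty", stacklevel=2)
    return retained, report


def select_one_eye_per_subject(cohort: Cohort, seed: int) -> Cohort:
    """Keep one randomly chosen eye per subject.

    Subjects contributing a single eligible eye keep it deterministically;
    for two-eyed subjects the choice is uniform and reproducible for a fixed
    seed.  Output preserves the input row order.
    """
    rng = substream(seed, "eye-selection")
    frame = cohort.frame
    keep = np.zeros(len(frame), dtype=bool)
    # iterate subjects in first-appearance order so the draw sequence is
    # a pure function of (cohort, seed)
    for _, idx in frame.groupby("subject_id", sort=False).indices.items():
        keep[idx[int(rng.integers(len(idx)))] if len(idx) > 1 else idx[0]] = True
    return cohort.subset(keep)
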