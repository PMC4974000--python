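"""Bennett ocular-magnification correction for OCT optic-disc area.

Fundus-image dimensions scale with the eye's optics; areas scale with the
square of the linear magnification.  Bennett's abbreviated-eye model gives
the linear scale factor ``p = 3.382 * 0.01306 * (AL - 1.82)`` for an eye of
axial length AL (mm), so

    true area = measured area * (3.382^2) * (0.01306^2) * (AL - 1.82)^2

The factor is exactly 1 at AL = 1.82 + 1/(3.382*0.01306) ~ 24.46 mm, i.e.
near-emmetropic eyes need almost no correction; longer (myopic) eyes have
their disc area scaled up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BennettConstants", "bennett_corrected_area", "correct_disc_area", "unit_axial_length"]


@dataclass(frozen=True)
class BennettConstants:
    camera_constant: float = 3.382    # instrument optics, dimensionless
    scale_constant: float = 0.01306   # per mm of axial length
    nodal_offset: float = 1.82        # mm, distance nodal point to anterior focal plane

    def __post_init__(self) -> None:
        if min(self.camera_constant, self.scale_constant, self.nodal_offset) <= 0:
            raise ValueError("Bennett constants must be positive")

    def area_factor(self, axial_length):
        al = np.asarray(axial_length, dtype=float)
        if np.any(al <= self.nodal_offset):
            raise ValueError(
                f"axial length must exceed {self.nodal_offset} mm "
                "(magnification model domain)"
            )
        lin = self.camera_constant * self.scale_constant * (al - self.nodal_offset)
        return lin * lin


DEFAULT_CONSTANTS = BennettConstants()


def unit_axial_length(constants: BennettConstants = DEFAULT_CONSTANTS) -> float:
    """Axial length at which the area correction factor equals exactly 1."""
    return constants.nodal_offset + 1.0 / (
        constants.camera_constant * constants.scale_constant
    )


def bennett_corrected_area(
    measured_area,
    axial_length,
    constants: BennettConstants = DEFAULT_CONSTANTS,
):
    """Magnification-corrected disc area (mm^2); scalar or elementwise.

    Exact arithmetic contract: ``measured_area * factor(AL)`` with no hidden
    rounding.  Raises ValueError when the axial length is at or below the
    nodal offset, or the measured area negative.
    """
    area = np.asarray(measured_area, dtype=float)
    if np.any(area < 0):
        raise ValueError("measured area must be non-negative")
    out = area * constants.area_factor(axial_length)
    return float(out) if out.ndim == 0 else out


def correct_disc_area(cohort, constants: BennettConstants = DEFAULT_CONSTANTS):
    """Return a cohort with ``disc_area_corrected`` filled in.

    The measured column is kept untouched; rows missing either input keep a
    missing corrected value.
    """
    from .cohort import Cohort  # local import avoids a cycle

    frame = cohort.frame.copy()
    ok = frame["disc_area_measured"].notna() & frame["axial_length"].notna()
    frame.loc[ok, "disc_area_corrected"] = bennett_corrected_area(
        frame.loc[ok, "disc_area_measured"].to_numpy(),
        frame.loc[ok, "axial_length"].to_numpy(),
        constants,
    )
    return Cohort(frame, provenance=cohort.provenance)
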