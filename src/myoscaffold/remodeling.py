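"""Remodeling index and fluorescence-reduction metrics.

The remodeling index (RI) compares peak ECM fluorescence at endomysial
locations of a control myoscaffold (no cells) against a cell-seeded
myoscaffold after culture.  Control and treated sections are different
physical samples, so locations cannot be paired; each treated location is
instead referenced to the control mean:

    RI_i = mean(control peak intensities) / treated peak intensity_i

RI close to 1 means the cells left the matrix essentially untouched; larger
RI means the seeded cells degraded the component.  The summary is the
arithmetic mean +- SD over treated locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "IntensitySet",
    "RemodelingIndexResult",
    "remodeling_index",
    "percent_reduction",
]


@dataclass(frozen=True)
class IntensitySet:
    """Per-location peak intensities for one condition.

    Any per-location scalar intensity works (pixel maximum or local
    line-scan peak); the two conventions differ only by a constant factor
    under the RI's scale invariance.
    """

    condition: str
    intensities: np.ndarray
    location_ids: tuple | None = None

    def __post_init__(self):
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", vals)
        if vals.size < 1:
            raise ValueError("intensity set needs >= 1 location")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(
                f"{self.condition}: intensities must be finite and positive"
            )
        if self.location_ids is not None and len(self.location_ids) != vals.size:
            raise ValueError("location_ids length mismatch")

    @property
    def n(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class RemodelingIndexResult:
    per_location_ri: np.ndarray
    mean_ri: float
    sd_ri: float
    n_locations: int
    orientation: str

    def summary(self) -> str:
        return (
            f"Remodeling index ({self.orientation}): "
            f"{self.mean_ri:.3g} +- {self.sd_ri:.3g} "
            f"(n = {self.n_locations} locations)"
        )


def remodeling_index(
    control: IntensitySet,
    treated: IntensitySet,
    orientation: Literal[
        "control_over_treated", "treated_over_control"
    ] = "control_over_treated",
) -> RemodelingIndexResult:
    """Per-location remodeling index with mean +- SD summary.

    The default orientation divides the control mean by each treated
    location, so degradation (lower treated intensity) gives RI > 1.  The
    reverse orientation is available for datasets recorded the other way
    round.
    """
    if orientation == "control_over_treated":
        ri = float(np.mean(control.intensities)) / treated.intensities
    elif orientation == "treated_over_control":
        ri = float(np.mean(treated.intensities)) / control.intensities
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    sd = float(np.std(ri, ddof=1)) if ri.size > 1 else 0.0
    return RemodelingIndexResult(
        per_location_ri=ri,
        mean_ri=float(np.mean(ri)),
        sd_ri=sd,
        n_locations=int(ri.size),
        orientation=orientation,
    )


def percent_reduction(intensity_t0: float, intensity_t: float) -> float:
    """Percent fluorescence reduction between two time points.

    100 * (I_t0 - I_t) / I_t0; negative when intensity increased.
    """
    if intensity_t0 <= 0:
        raise ValueError("initial intensity must be positive")
    return 100.0 * (intensity_t0 - intensity_t) / intensity_t0
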