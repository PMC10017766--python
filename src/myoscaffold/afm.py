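"""AFM force-curve mechanics: Hertz-Sneddon modulus and rupture force.

The approach segment of a force-separation curve is fitted with the Sneddon
contact relation for a conical indenter,

    F = C(alpha, nu) * E * delta^2,      C = (2/pi) * tan(alpha) / (1 - nu^2)

with indentation delta = contact_point - separation, tip half-angle alpha and
Poisson ratio nu (0.5 by default, the incompressible soft-matter limit).
Pyramidal probes are handled either as an equivalent cone or with the
four-sided-pyramid constant 0.7453 tan(alpha) — the two geometries differ
only by this constant factor.

With forces in nN and separations in um, the fitted E comes out directly in
nN/um^2 = kPa.

The rupture (adhesive) force is the magnitude of the deepest
baseline-corrected negative excursion of the retraction segment before
pull-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ForceCurve",
    "TipModel",
    "MechanicsResult",
    "ContactPoint",
    "detect_contact_point",
    "fit_hertz_sneddon",
    "rupture_force",
    "batch_summary",
    "HertzSneddonModel",
    "hertz_coefficient",
]

MIN_SEGMENT_SAMPLES = 50
DEFAULT_TRIGGER_FORCE_NN = 3.0


@dataclass(frozen=True)
class ForceCurve:
    """One AFM segment: force (nN) versus tip-sample separation (um).

    Samples are stored in acquisition order — separation decreasing on
    approach, increasing on retraction.  Metadata carries acquisition
    settings (trigger force, speed, probe spring constant).
    """

    segment: Literal["approach", "retract"]
    separation: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        sep = np.asarray(self.separation, dtype=float)
        frc = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "separation", sep)
        object.__setattr__(self, "force", frc)
        if self.segment not in ("approach", "retract"):
            raise ValueError(f"unknown segment {self.segment!r}")
        if sep.shape != frc.shape or sep.ndim != 1:
            raise ValueError("separation and force must be 1D, same length")
        if sep.size < MIN_SEGMENT_SAMPLES:
            raise ValueError(
                f"segment needs >= {MIN_SEGMENT_SAMPLES} samples, got {sep.size}"
            )
        if not (np.all(np.isfinite(sep)) and np.all(np.isfinite(frc))):
            raise ValueError("non-finite separation/force value")

    @property
    def trigger_force(self) -> float:
        return float(self.metadata.get("trigger_force_nN",
                                       DEFAULT_TRIGGER_FORCE_NN))


@dataclass(frozen=True)
class TipModel:
    """Indenter geometry for the Sneddon contact relation."""

    geometry: Literal["cone", "pyramid"] = "cone"
    half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5

    def __post_init__(self):
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half angle must lie in (0, 90) degrees")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")


def hertz_coefficient(tip: TipModel) -> float:
    """C such that F[nN] = C * E[kPa] * delta[um]^2."""
    tan_a = math.tan(math.radians(tip.half_angle_deg))
    if tip.geometry == "cone":
        geom = (2.0 / math.pi) * tan_a
    elif tip.geometry == "pyramid":
        geom = 0.7453 * tan_a  # four-sided pyramid (Bilodeau constant)
    else:
        raise ValueError(f"unknown geometry {tip.geometry!r}")
    return geom / (1.0 - tip.poisson_ratio**2)


@dataclass(frozen=True)
class ContactPoint:
    separation_um: float
    index: int
    baseline_slope: float
    baseline_intercept: float
    noise_sd: float


@dataclass
class MechanicsResult:
    """Fitted modulus and adhesion readouts for one location."""

    young_modulus_kpa: float
    contact_point_um: float
    fit_range_um: tuple[float, float]  # indentation interval used
    fit_rss: float
    n_points: int
    rupture_force_nn: float | None = None
    tip: TipModel | None = None
    group: str | None = None

    @property
    def young_modulus_pa(self) -> float:
        return self.young_modulus_kpa * 1e3

    def summary(self) -> str:
        lines = [
            "Hertz-Sneddon fit",
            "=================",
            f"Young's modulus : {self.young_modulus_kpa:.4g} kPa",
            f"contact point   : {self.contact_point_um:.4g} um",
            f"fit range       : {self.fit_range_um[0]:.3g}-"
            f"{self.fit_range_um[1]:.3g} um indentation "
            f"({self.n_points} points, RSS {self.fit_rss:.3g} nN^2)",
        ]
        if self.rupture_force_nn is not None:
            lines.append(f"rupture force   : {self.rupture_force_nn:.4g} nN")
        return "\n".join(lines)


def _baseline(curve: ForceCurve, fraction: float, end: str):
    """Least-squares line over the off-surface portion of a segment."""
    n = curve.separation.size
    m = max(10, int(round(fraction * n)))
    sl = slice(0, m) if end == "head" else slice(n - m, n)
    s, f = curve.separation[sl], curve.force[sl]
    slope, intercept = np.polyfit(s, f, 1)
    resid = f - (slope * s + intercept)
    return float(slope), float(intercept), float(np.std(resid))


def detect_contact_point(
    approach: ForceCurve,
    threshold_factor: float = 5.0,
    sustained_samples: int = 5,
    baseline_fraction: float = 0.3,
) -> ContactPoint:
    """Locate tip-sample contact on the approach segment.

    A least-squares line over the first ``baseline_fraction`` of the segment
    (the off-surface region, including any tilt) is subtracted.  The first
    sample whose corrected force exceeds ``threshold_factor`` times the
    baseline noise SD and stays above for ``sustained_samples`` samples marks
    unambiguous contact; the contact point is then backtracked to where the
    corrected force last left the baseline, which removes the depth bias the
    threshold alone would introduce on noisy curves.
    """
    if approach.segment != "approach":
        raise ValueError("contact detection expects the approach segment")
    slope, intercept, noise_sd = _baseline(approach, baseline_fraction, "head")
    floor = 1e-9 * max(1.0, float(np.max(np.abs(approach.force))))
    m = sustained_samples
    result = None
    # two passes: once the contact sample is known, the baseline line is
    # refit over the whole pre-contact region, which roughly halves the
    # extrapolated tilt error under the contact data
    for _ in range(2):
        corrected = approach.force - (slope * approach.separation + intercept)
        threshold = threshold_factor * max(noise_sd, floor)
        above = corrected > threshold
        hit = None
        for i in range(above.size - m + 1):
            if above[i:i + m].all():
                hit = i
                break
        if hit is None:
            raise ValueError("no contact detected")
        j = hit
        while j > 0 and corrected[j - 1] > 0:
            j -= 1
        result = ContactPoint(float(approach.separation[j]), j,
                              slope, intercept, noise_sd)
        if j < 20:  # not enough pre-contact samples to improve the line
            break
        pre = slice(0, max(10, j - m))
        s, f = approach.separation[pre], approach.force[pre]
        slope, intercept = np.polyfit(s, f, 1)
        noise_sd = float(np.std(f - (slope * s + intercept)))
    return result


def fit_hertz_sneddon(
    approach: ForceCurve,
    tip: TipModel = TipModel(),
    contact: ContactPoint | None = None,
    trigger_force: float | None = None,
    refine_contact: bool = True,
    min_points: int = 10,
) -> MechanicsResult:
    """Least-squares Hertz-Sneddon fit of the approach segment.

    Fits F = C * E * delta^2 over baseline-corrected forces in
    (0, trigger_force] (mirroring the acquisition protocol, which ramps until
    the trigger force is reached).  When ``refine_contact`` is set the
    contact point is co-refined as a free offset, which removes the
    half-sample bias of threshold-based detection.
    """
    if contact is None:
        contact = detect_contact_point(approach)
    trigger = approach.trigger_force if trigger_force is None else trigger_force
    coef = hertz_coefficient(tip)
    corrected = approach.force - (
        contact.baseline_slope * approach.separation + contact.baseline_intercept
    )
    delta = contact.separation_um - approach.separation
    if not np.any(delta > 0):
        raise ValueError("no indentation region (delta > 0) in fit range")
    dmax = float(np.max(delta))
    spacing = float(np.median(np.abs(np.diff(approach.separation))))
    # when the contact point is co-refined, a band on either side of the
    # detected contact enters the fit and clip(delta - dc, 0) absorbs the
    # pre-contact part; this keeps threshold-detection bias out of E
    margin = max(10 * spacing, dmax) if refine_contact else 0.0
    mask = (delta > -margin) & (corrected <= trigger)
    d, f = delta[mask], corrected[mask]
    if int(np.sum(d > 0)) < min_points:
        raise ValueError(
            f"only {int(np.sum(d > 0))} indentation points in fit range "
            f"(< {min_points})"
        )
    # linear-in-E estimate over the deep-contact half as starting value
    deep = d > 0.5 * dmax
    e0 = float(np.sum(f[deep] * d[deep] ** 2)
               / (coef * np.sum(d[deep] ** 4)))
    if refine_contact:
        # profile the contact offset: for any dc the best E is a linear
        # least-squares solution, so the search is one-dimensional and
        # immune to the flat gradients of the clipped quadratic
        def best_e(dc):
            shifted = np.clip(d - dc, 0.0, None)
            s4 = float(np.sum(shifted**4))
            if s4 <= 0:
                return 0.0
            return float(np.sum(f * shifted**2) / (coef * s4))

        def rss(dc):
            shifted = np.clip(d - dc, 0.0, None)
            return float(np.sum((f - coef * best_e(dc) * shifted**2) ** 2))

        opt = optimize.minimize_scalar(
            rss, bounds=(-margin, margin), method="bounded",
            options={"xatol": 1e-6 * max(dmax, 1.0)},
        )
        dc = float(opt.x)
        e_fit = best_e(dc)
        resid = f - coef * e_fit * np.clip(d - dc, 0.0, None) ** 2
        contact_sep = contact.separation_um - dc
        fit_lo, fit_hi = 0.0, float(np.max(d - dc))
    else:
        e_fit, dc = e0, 0.0
        resid = f - coef * e_fit * d**2
        contact_sep = contact.separation_um
        fit_lo, fit_hi = float(d[d > 0].min()), float(d.max())
    if e_fit <= 0:
        raise ValueError(
            f"non-positive fitted modulus ({e_fit:.3g} kPa); "
            f"RSS {float(np.sum(resid**2)):.3g} nN^2"
        )
    return MechanicsResult(
        young_modulus_kpa=e_fit,
        contact_point_um=contact_sep,
        fit_range_um=(max(fit_lo, 0.0), fit_hi),
        fit_rss=float(np.sum(resid**2)),
        n_points=int(d.size),
        tip=tip,
    )


def rupture_force(
    retract: ForceCurve,
    threshold_factor: float = 3.0,
    baseline_fraction: float = 0.3,
    smooth_window: int = 5,
) -> float:
    """Peak rupture force (nN) during retraction.

    Magnitude of the deepest negative excursion of the baseline-corrected
    retraction force; adhesion appears as a dip below the post-pull-off
    baseline (fitted over the final ``baseline_fraction`` of the segment).
    On noisy curves the trace is lightly smoothed (``smooth_window``-sample
    moving average) before the extremum is taken — the raw minimum of a
    long noisy trace overstates the dip by the expected extreme of the
    noise.  Returns 0 when no dip exceeds ``threshold_factor`` x baseline
    noise SD.
    """
    if retract.segment != "retract":
        raise ValueError("rupture force expects the retraction segment")
    slope, intercept, noise_sd = _baseline(retract, baseline_fraction, "tail")
    corrected = retract.force - (slope * retract.separation + intercept)
    floor = 1e-9 * max(1.0, float(np.max(np.abs(retract.force))))
    if noise_sd > floor and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        corrected = np.convolve(corrected, kernel, mode="same")
    threshold = threshold_factor * max(noise_sd, floor)
    depth = -float(np.min(corrected))
    return depth if depth > threshold else 0.0


class HertzSneddonModel:
    """Model object pairing an approach (and optional retraction) segment
    with a tip geometry; fit() returns a `MechanicsResult`."""

    def __init__(
        self,
        approach: ForceCurve,
        retract: ForceCurve | None = None,
        tip: TipModel = TipModel(),
        *,
        refine_contact: bool = True,
        trigger_force: float | None = None,
    ):
        self.approach = approach
        self.retract = retract
        self.tip = tip
        self.refine_contact = refine_contact
        self.trigger_force = trigger_force

    def fit(self) -> MechanicsResult:
        result = fit_hertz_sneddon(
            self.approach, self.tip,
            trigger_force=self.trigger_force,
            refine_contact=self.refine_contact,
        )
        if self.retract is not None:
            result.rupture_force_nn = rupture_force(self.retract)
        return result


def batch_summary(
    results: Sequence[MechanicsResult],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean +- SD of modulus and rupture force.

    Aggregation is over individual curves within each group (one row per
    group), matching per-sample averaging of point grids.
    """
    if len(results) == 0:
        raise ValueError("no results to summarise")
    if groups is None:
        groups = [r.group if r.group is not None else "all" for r in results]
    if len(groups) != len(results):
        raise ValueError("groups length mismatch")
    df = pd.DataFrame({
        "group": list(groups),
        "young_modulus_kpa": [r.young_modulus_kpa for r in results],
        "rupture_force_nn": [
            np.nan if r.rupture_force_nn is None else r.rupture_force_nn
            for r in results
        ],
    })
    if (df.groupby("group").size() < 1).any():
        raise ValueError("empty group")
    out = df.groupby("group").agg(
        n=("young_modulus_kpa", "size"),
        modulus_mean_kpa=("young_modulus_kpa", "mean"),
        modulus_sd_kpa=("young_modulus_kpa", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        rupture_mean_nn=("rupture_force_nn", "mean"),
        rupture_sd_nn=("rupture_force_nn", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
    ).reset_index()
    return out
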