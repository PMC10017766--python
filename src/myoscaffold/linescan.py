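"""Segmentation of endomysial line scans into basement membrane and interstitial matrix.

A line scan drawn perpendicular to the endomysium between two adjacent
myofibers crosses two basement membranes (BM, laminin-rich, one per fiber)
with the interstitial matrix (IM, fibrillar collagens/fibronectin) in
between.  In a two-channel fluorescence profile the red channel (laminin
alpha-2) therefore shows two peaks over a baseline; the green channel carries
the co-stained ECM component whose BM/IM partitioning is the quantity of
interest.

The analysis chain is:

1. basal scaling — estimate and subtract the background (basal) intensity of
   each channel, clipping negatives to zero;
2. zero-phase low-pass smoothing (Butterworth, forward-backward);
3. locate the two dominant red peaks;
4. fit each peak with a single Gaussian or a two-Gaussian mixture, chosen by
   BIC;
5. place four segment points at the effective mean +- 2 effective SD of each
   fitted peak (~95.45% of the fitted mass), defining BM = [s1,s2] u [s3,s4]
   and IM = [s2,s3];
6. integrate each channel (trapezoid) over the three regions to obtain
   abundances in intensity*um, the red-derived segment points being applied
   unchanged to the green channel;
7. report the green/red BM abundance ratio as the relative stoichiometry of
   the co-stained component against laminin alpha-2.

`LineScanModel` bundles the chain behind a statsmodels-style fit() that
returns a `LineScanResults` carrying every intermediate for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, signal

__all__ = [
    "LineScanProfile",
    "FilterSettings",
    "GaussianPeakFit",
    "SegmentPoints",
    "RegionAbundance",
    "LineScanModel",
    "LineScanResults",
    "LineScanError",
    "NoDistinctPeaksError",
    "scale_to_basal",
    "smooth",
    "find_two_peaks",
    "fit_peak",
    "segment_points",
    "region_abundance",
    "stoichiometry",
    "analyze_linescan",
    "sample_regions",
    "gaussian",
    "gaussian_window_integral",
    "trapezoid_between",
]

MIN_SAMPLES = 32


class LineScanError(Exception):
    """Stage-tagged failure inside the line-scan pipeline."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if stage else message)


class NoDistinctPeaksError(LineScanError):
    """Raised when the red channel lacks two distinct basement-membrane peaks."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineScanProfile:
    """Two-channel intensity trace across one endomysial span.

    position : um, strictly increasing, ~uniform spacing
    red      : laminin alpha-2 channel intensity (>= 0)
    green    : co-stained ECM component channel intensity (>= 0)
    """

    position: np.ndarray
    red: np.ndarray
    green: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        red = np.asarray(self.red, dtype=float)
        green = np.asarray(self.green, dtype=float)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "red", red)
        object.__setattr__(self, "green", green)
        if pos.ndim != 1 or pos.size < MIN_SAMPLES:
            raise ValueError(
                f"profile needs >= {MIN_SAMPLES} samples, got {pos.size}"
            )
        if red.shape != pos.shape or green.shape != pos.shape:
            raise ValueError("red/green length must match position")
        for name, arr in (("position", pos), ("red", red), ("green", green)):
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite {name} value at row {row}")
        if np.any(np.diff(pos) <= 0):
            row = int(np.flatnonzero(np.diff(pos) <= 0)[0] + 1)
            raise ValueError(f"positions not strictly increasing at row {row}")

    @property
    def spacing(self) -> float:
        """Median sample spacing in um."""
        return float(np.median(np.diff(self.position)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.position[0]), float(self.position[-1])

    def with_channels(self, red: np.ndarray, green: np.ndarray,
                      extra_flags: Sequence[str] = ()) -> "LineScanProfile":
        return LineScanProfile(self.position, red, green,
                               tuple(self.flags) + tuple(extra_flags))


@dataclass(frozen=True)
class FilterSettings:
    """Zero-phase Butterworth low-pass design used for smoothing."""

    filter_order: int = 3
    cutoff_fraction: float = 0.2  # fraction of Nyquist

    def __post_init__(self):
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0 < self.cutoff_fraction < 1:
            raise ValueError("cutoff_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class GaussianPeakFit:
    """Selected gauss1/gauss2 fit of one basement-membrane peak.

    components hold (amplitude, mean um, sd um) per Gaussian term.  For a
    two-component fit the effective mean/SD are the mixture (area-weighted)
    first and second moments; the +-2 SD segment window is placed on these.
    """

    model_order: int
    components: tuple[tuple[float, float, float], ...]
    effective_mean: float
    effective_sd: float
    fit_rss: float
    selection_score: float  # BIC(gauss1) - BIC(gauss2); > margin selects gauss2

    @property
    def window(self) -> tuple[float, float]:
        return (self.effective_mean - 2 * self.effective_sd,
                self.effective_mean + 2 * self.effective_sd)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for amp, mu, sd in self.components:
            out += gaussian(x, amp, mu, sd)
        return out


@dataclass(frozen=True)
class SegmentPoints:
    """Four segment points: BM regions [s1,s2], [s3,s4]; IM region [s2,s3]."""

    s1: float
    s2: float
    s3: float
    s4: float
    no_distinct_im: bool = False

    def __post_init__(self):
        if not (self.s1 < self.s2 <= self.s3 < self.s4):
            raise ValueError(
                f"segment points must satisfy s1 < s2 <= s3 < s4, got "
                f"({self.s1}, {self.s2}, {self.s3}, {self.s4})"
            )


@dataclass(frozen=True)
class RegionAbundance:
    """Per-region abundances in intensity*um for one channel."""

    bm_left: float
    im: float
    bm_right: float
    peak_bm_intensity: float

    @property
    def bm_total(self) -> float:
        return self.bm_left + self.bm_right

    @property
    def total(self) -> float:
        return self.bm_left + self.im + self.bm_right


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def gaussian(x, amplitude, mean, sd):
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))


def gaussian_window_integral(amplitude: float, sd: float,
                             lo: float, hi: float, mean: float) -> float:
    """Closed-form integral of an (unnormalised) Gaussian over [lo, hi]."""
    from scipy.special import erf

    z = 1.0 / (sd * math.sqrt(2.0))
    return amplitude * sd * math.sqrt(math.pi / 2.0) * (
        erf((hi - mean) * z) - erf((lo - mean) * z)
    )


def trapezoid_between(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of sampled y(x) over [lo, hi].

    Endpoints falling between samples are linearly interpolated, so the sum
    of integrals over adjacent intervals equals the integral over their union
    to machine precision.
    """
    if hi <= lo:
        return 0.0
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = max(lo, float(x[0]))
    hi = min(hi, float(x[-1]))
    if hi <= lo:
        return 0.0
    inner = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]))
    return float(np.trapezoid(ys, xs))


def _clipped_mean_baseline(values: np.ndarray, k: float = 2.0,
                           max_iter: int = 30) -> float:
    """Iteratively sigma-clipped mean: robust estimate of the background
    level of a trace made of a flat dim baseline plus bright structure.

    The iteration starts from the lowest quartile so it locks onto the dim
    background even when peaks and plateaus occupy most of the span.
    """
    vals = np.asarray(values, dtype=float)
    sel = vals <= np.percentile(vals, 25)
    for _ in range(max_iter):
        center = np.median(vals[sel])
        scale = 1.4826 * np.median(np.abs(vals[sel] - center))
        if scale == 0:
            return float(center)
        new = np.abs(vals - center) <= k * scale
        if new.sum() < 8 or np.array_equal(new, sel):
            sel = new if new.sum() >= 8 else sel
            break
        sel = new
    return float(np.mean(vals[sel]))


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def estimate_basal(
    channel: np.ndarray,
    basal_percentile: float = 5.0,
    basal_method: Literal["clipped_mean", "percentile"] = "clipped_mean",
) -> float:
    """Basal (background) level of one channel.

    "clipped_mean" (default) is an iterative sigma-clipped mean, unbiased
    for the background level under additive noise; "percentile" takes the
    basal_percentile-th percentile (simpler, but biased low by O(noise SD)).
    """
    if basal_method == "percentile":
        return float(np.percentile(channel, basal_percentile))
    if basal_method == "clipped_mean":
        return _clipped_mean_baseline(np.asarray(channel, dtype=float))
    raise ValueError(f"unknown basal_method {basal_method!r}")


def scale_to_basal(
    profile: LineScanProfile,
    basal_percentile: float = 5.0,
    basal_method: Literal["clipped_mean", "percentile"] = "clipped_mean",
) -> LineScanProfile:
    """Subtract each channel's basal (background) value and clip at zero.

    Subtraction (rather than division) keeps downstream areas in
    intensity*um.  A constant-zero channel is returned unchanged and flagged.
    """
    flags = []
    out = {}
    for name, chan in (("red", profile.red), ("green", profile.green)):
        if np.all(chan == 0):
            flags.append(f"{name}_channel_constant_zero")
            out[name] = chan.copy()
            continue
        basal = estimate_basal(chan, basal_percentile, basal_method)
        out[name] = np.clip(chan - basal, 0.0, None)
    return profile.with_channels(out["red"], out["green"], flags)


def smooth(profile: LineScanProfile,
           settings: FilterSettings = FilterSettings()) -> LineScanProfile:
    """Zero-phase Butterworth low-pass smoothing of both channels.

    The filter is applied forward then backward (filtfilt) so the output has
    no phase lag: a symmetric input stays symmetric and clean peak positions
    shift by less than one sample spacing.
    """
    b, a = signal.butter(settings.filter_order, settings.cutoff_fraction)
    padlen = 3 * max(len(a), len(b))
    n = profile.position.size
    if n <= 3 * padlen:
        raise LineScanError(
            f"profile too short for zero-phase filtering: need > {3 * padlen} "
            f"samples, got {n}",
            stage="smooth",
        )
    red = signal.filtfilt(b, a, profile.red)
    green = signal.filtfilt(b, a, profile.green)
    return profile.with_channels(red, green)


def find_two_peaks(
    position: np.ndarray,
    values: np.ndarray,
    min_separation: float,
    prominence_fraction: float = 0.05,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Locate the two highest local maxima separated by >= min_separation um.

    Candidate maxima must be distinct: their topographic prominence must
    exceed ``prominence_fraction`` of the trace's dynamic range, which
    suppresses residual noise ripples riding on a single physical peak.
    Returns ((pos_left, height_left), (pos_right, height_right)).  Equal
    heights tie-break to the leftmost position.  Raises
    `NoDistinctPeaksError` when fewer than two qualifying maxima exist —
    spans lacking a distinct basement membrane are excluded from analysis.
    """
    position = np.asarray(position, dtype=float)
    values = np.asarray(values, dtype=float)
    prominence = None
    if prominence_fraction > 0:
        prominence = prominence_fraction * float(np.ptp(values))
        prominence = prominence if prominence > 0 else None
    idx, _ = signal.find_peaks(values, prominence=prominence)
    if idx.size < 2:
        raise NoDistinctPeaksError(
            "no distinct basement membrane peaks", stage="find_two_peaks"
        )
    # sort candidates by height desc, position asc (leftmost tie-break)
    order = sorted(idx, key=lambda i: (-values[i], position[i]))
    first = order[0]
    second = None
    for i in order[1:]:
        if abs(position[i] - position[first]) >= min_separation:
            second = i
            break
    if second is None:
        raise NoDistinctPeaksError(
            "no distinct basement membrane peaks", stage="find_two_peaks"
        )
    pair = sorted((first, second), key=lambda i: position[i])
    return tuple((float(position[i]), float(values[i])) for i in pair)


def _fit_one_order(x, y, order, apex_pos, apex_height, width0):
    """curve_fit one gauss model order; returns (params, rss) or None."""
    lo, hi = float(x[0]), float(x[-1])
    span = hi - lo
    ymax = max(float(np.max(y)), 1e-12)
    if order == 1:
        p0 = [apex_height, apex_pos, width0]
        bounds = ([0.0, lo, width0 * 0.05], [4 * ymax, hi, span])
        model = lambda x, a, m, s: gaussian(x, a, m, s)  # noqa: E731
    else:
        d = max(width0 * 0.6, span * 0.02)
        p0 = [apex_height * 0.6, apex_pos - d, width0 * 0.8,
              apex_height * 0.6, apex_pos + d, width0 * 0.8]
        bounds = ([0.0, lo, width0 * 0.05] * 2, [4 * ymax, hi, span] * 2)
        model = lambda x, a1, m1, s1, a2, m2, s2: (  # noqa: E731
            gaussian(x, a1, m1, s1) + gaussian(x, a2, m2, s2)
        )
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                     maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    return popt, rss


def _gauss2_is_valid(popt, apex_pos, width0, reach: float = 2.0,
                     min_weight: float = 0.05) -> bool:
    """Whether a two-component fit describes the apex peak itself.

    Rejects fits whose second component wandered off to model baseline
    structure: component means must lie within ``reach`` FWHM-equivalent
    half-widths of the apex and each component must carry at least
    ``min_weight`` of the total area.
    """
    comps = [(popt[3 * i], popt[3 * i + 1], popt[3 * i + 2]) for i in range(2)]
    weights = [a * s for a, _, s in comps]
    total = sum(weights)
    if total <= 0:
        return False
    half_width = 2.355 * width0  # FWHM from the crude width estimate
    for (a, mu, s), w in zip(comps, weights):
        if abs(mu - apex_pos) > reach * half_width:
            return False
        if w / total < min_weight:
            return False
    return True


def _mixture_moments(components):
    """Area-weighted mean and SD of a Gaussian mixture."""
    w = np.array([a * s for a, _, s in components], dtype=float)
    if w.sum() <= 0:
        raise ValueError("degenerate mixture (non-positive total area)")
    w = w / w.sum()
    mu = np.array([m for _, m, _ in components], dtype=float)
    sd = np.array([s for _, _, s in components], dtype=float)
    mean = float(np.sum(w * mu))
    var = float(np.sum(w * (sd**2 + (mu - mean) ** 2)))
    return mean, math.sqrt(var)


def fit_peak(
    position: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
    bic_margin: float = 2.0,
) -> GaussianPeakFit:
    """Fit one BM peak with gauss1 and gauss2; keep the BIC-preferred model.

    Both model classes are fitted by nonlinear least squares inside
    ``window``.  BIC is computed from the RSS under Gaussian residuals
    (n*ln(RSS/n) + k*ln n); the two-component model is kept only when it
    lowers BIC by more than ``bic_margin``, biasing selection toward the
    simpler description of the peak.  A two-component fit must also be a
    valid description of *this* peak: both component means must lie within
    two half-widths of the apex and neither component may carry a negligible
    share (< 5%) of the total area — otherwise the extra component is
    fitting baseline structure and gauss1 is kept.
    """
    position = np.asarray(position, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = window
    mask = (position >= lo) & (position <= hi)
    x, y = position[mask], values[mask]
    if x.size < 8:
        raise LineScanError(
            f"fit window [{lo:g}, {hi:g}] holds {x.size} samples (< 8)",
            stage="fit_peak",
        )
    apex = int(np.argmax(y))
    if apex == 0 or apex == x.size - 1:
        raise LineScanError("window does not contain the peak apex",
                            stage="fit_peak")
    apex_pos, apex_height = float(x[apex]), float(y[apex])
    # crude width from half maximum
    above = y >= apex_height / 2.0
    width0 = max(float(x[above][-1] - x[above][0]) / 2.355,
                 float(np.median(np.diff(x))))

    n = x.size
    fits = {}
    for order, k in ((1, 3), (2, 6)):
        res = _fit_one_order(x, y, order, apex_pos, apex_height, width0)
        if res is None:
            continue
        popt, rss = res
        if order == 2 and not _gauss2_is_valid(popt, apex_pos, width0):
            continue
        scale = max(float(np.max(np.abs(y))), 1.0)
        rss_floor = n * (1e-10 * scale) ** 2
        bic = n * math.log(max(rss, rss_floor) / n) + k * math.log(n)
        fits[order] = (popt, rss, bic)
    if not fits:
        raise LineScanError(
            "nonlinear fit failed for both gauss1 and gauss2 in window "
            f"[{lo:g}, {hi:g}]",
            stage="fit_peak",
        )
    if 1 in fits and 2 in fits:
        score = fits[1][2] - fits[2][2]
        order = 2 if score > bic_margin else 1
    else:
        order = next(iter(fits))
        score = math.inf if order == 2 else -math.inf
    popt, rss, _ = fits[order]
    comps = tuple(
        (float(popt[3 * i]), float(popt[3 * i + 1]), float(popt[3 * i + 2]))
        for i in range(order)
    )
    mean, sd = _mixture_moments(comps)
    return GaussianPeakFit(order, comps, mean, sd, rss, float(score))


def segment_points(
    left_fit: GaussianPeakFit,
    right_fit: GaussianPeakFit,
    span: tuple[float, float] | None = None,
) -> SegmentPoints:
    """Place the four segment points at effective mean +- 2 effective SD.

    Two SDs capture ~95.45% of each fitted peak's mass.  If the two BM
    windows overlap (s2 > s3) the overlap midpoint is assigned to both and
    the result is flagged ``no_distinct_im`` — fibrotic spans with expanded
    laminin still yield BM abundances.
    """
    s1, s2 = left_fit.window
    s3, s4 = right_fit.window
    flagged = False
    if s2 > s3:
        mid = 0.5 * (s2 + s3)
        s2 = s3 = mid
        flagged = True
    if span is not None and (s1 < span[0] or s4 > span[1]):
        raise LineScanError("peak window exceeds scan", stage="segment_points")
    return SegmentPoints(s1, s2, s3, s4, no_distinct_im=flagged)


def region_abundance(
    position: np.ndarray,
    values: np.ndarray,
    points: SegmentPoints,
) -> RegionAbundance:
    """Trapezoidal AUC of one channel over the BM and IM regions (I*um)."""
    position = np.asarray(position, dtype=float)
    values = np.asarray(values, dtype=float)
    bm_left = max(trapezoid_between(position, values, points.s1, points.s2), 0.0)
    im = max(trapezoid_between(position, values, points.s2, points.s3), 0.0)
    bm_right = max(trapezoid_between(position, values, points.s3, points.s4), 0.0)
    in_bm = ((position >= points.s1) & (position <= points.s2)) | (
        (position >= points.s3) & (position <= points.s4)
    )
    peak = float(np.max(values[in_bm])) if np.any(in_bm) else 0.0
    return RegionAbundance(bm_left, im, bm_right, peak)


def stoichiometry(
    red_abundance: RegionAbundance,
    green_abundance: RegionAbundance,
    convention: Literal["green_over_red", "red_over_green"] = "green_over_red",
) -> float:
    """BM abundance ratio between the co-stained component and laminin alpha-2.

    The default convention is green BM AUC / red BM AUC, so a component that
    perfectly co-localises with laminin at equal (scaled) intensity gives 1.
    """
    if red_abundance.bm_total <= 0:
        raise LineScanError("red BM abundance is zero; stoichiometry undefined",
                            stage="stoichiometry")
    if convention == "green_over_red":
        return green_abundance.bm_total / red_abundance.bm_total
    if convention == "red_over_green":
        if green_abundance.bm_total <= 0:
            raise LineScanError("green BM abundance is zero", stage="stoichiometry")
        return red_abundance.bm_total / green_abundance.bm_total
    raise ValueError(f"unknown stoichiometry convention {convention!r}")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


@dataclass
class LineScanResults:
    """Everything the line-scan analysis produced, intermediates included."""

    profile: LineScanProfile
    scaled: LineScanProfile
    smoothed: LineScanProfile
    left_fit: GaussianPeakFit
    right_fit: GaussianPeakFit
    points: SegmentPoints
    red_abundance: RegionAbundance
    green_abundance: RegionAbundance
    stoichiometry_ratio: float
    params: dict = field(default_factory=dict)

    @property
    def flags(self) -> tuple[str, ...]:
        flags = tuple(self.scaled.flags)
        if self.points.no_distinct_im:
            flags += ("no_distinct_im",)
        return flags

    def to_dict(self) -> dict:
        def _fit(f: GaussianPeakFit) -> dict:
            return {
                "model_order": f.model_order,
                "components": [list(c) for c in f.components],
                "effective_mean_um": f.effective_mean,
                "effective_sd_um": f.effective_sd,
                "fit_rss": f.fit_rss,
                "selection_score": f.selection_score,
            }

        def _ab(a: RegionAbundance) -> dict:
            return {
                "bm_left_I_um": a.bm_left,
                "im_I_um": a.im,
                "bm_right_I_um": a.bm_right,
                "bm_total_I_um": a.bm_total,
                "peak_bm_intensity": a.peak_bm_intensity,
            }

        return {
            "segment_points_um": [self.points.s1, self.points.s2,
                                  self.points.s3, self.points.s4],
            "left_fit": _fit(self.left_fit),
            "right_fit": _fit(self.right_fit),
            "red": _ab(self.red_abundance),
            "green": _ab(self.green_abundance),
            "stoichiometry_ratio": self.stoichiometry_ratio,
            "flags": list(self.flags),
            "params": self.params,
        }

    def summary(self) -> str:
        p = self.points
        lines = [
            "Line-scan segmentation",
            "======================",
            f"segment points s1..s4 (um): {p.s1:.3g}, {p.s2:.3g}, {p.s3:.3g}, {p.s4:.3g}",
            f"left peak : gauss{self.left_fit.model_order}, "
            f"mean {self.left_fit.effective_mean:.3g} um, "
            f"sd {self.left_fit.effective_sd:.3g} um",
            f"right peak: gauss{self.right_fit.model_order}, "
            f"mean {self.right_fit.effective_mean:.3g} um, "
            f"sd {self.right_fit.effective_sd:.3g} um",
            "",
            "abundance (I*um)   BM left      IM        BM right   BM total",
            f"red   {self.red_abundance.bm_left:12.4g} {self.red_abundance.im:10.4g}"
            f" {self.red_abundance.bm_right:10.4g} {self.red_abundance.bm_total:10.4g}",
            f"green {self.green_abundance.bm_left:12.4g} {self.green_abundance.im:10.4g}"
            f" {self.green_abundance.bm_right:10.4g} {self.green_abundance.bm_total:10.4g}",
            "",
            f"stoichiometry (green/red BM): {self.stoichiometry_ratio:.3g}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot scaled channels, fits, and segment points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.smoothed.position
        ax.plot(x, self.smoothed.red, color="tab:red", label="red (laminin a2)")
        ax.plot(x, self.smoothed.green, color="tab:green", label="green")
        model = self.left_fit(x) + self.right_fit(x)
        ax.plot(x, model, "k--", lw=1, label="fitted peaks")
        for s in (self.points.s1, self.points.s2, self.points.s3, self.points.s4):
            ax.axvline(s, color="gray", ls=":", lw=0.8)
        ax.set_xlabel("position (um)")
        ax.set_ylabel("intensity (basal-scaled)")
        ax.legend(frameon=False)
        return ax


class LineScanModel:
    """Statsmodels-style model wrapping the full segmentation chain.

    Parameters
    ----------
    profile : LineScanProfile
    basal_percentile : percentile used when basal_method="percentile"
    basal_method : "clipped_mean" (default) or "percentile"
    filter_settings : zero-phase Butterworth design
    min_separation : minimum peak separation in um
        (default 4 x median sample spacing)
    bic_margin : BIC improvement required to prefer gauss2 over gauss1
    refine_background : measure the residual background of each channel on
        the structure-free exterior of the fitted BM windows and remove it
        before integration (second pass; default True)
    stoichiometry_convention : "green_over_red" (default) or "red_over_green"
    """

    def __init__(
        self,
        profile: LineScanProfile,
        *,
        basal_percentile: float = 5.0,
        basal_method: Literal["clipped_mean", "percentile"] = "clipped_mean",
        filter_settings: FilterSettings = FilterSettings(),
        min_separation: float | None = None,
        bic_margin: float = 2.0,
        refine_background: bool = True,
        stoichiometry_convention: Literal[
            "green_over_red", "red_over_green"] = "green_over_red",
    ):
        self.profile = profile
        self.basal_percentile = basal_percentile
        self.basal_method = basal_method
        self.filter_settings = filter_settings
        self.min_separation = (
            4.0 * profile.spacing if min_separation is None else min_separation
        )
        self.bic_margin = bic_margin
        self.refine_background = refine_background
        self.stoichiometry_convention = stoichiometry_convention

    @classmethod
    def from_dataframe(cls, frame, *, position="position", red="red",
                       green="green", **kwargs) -> "LineScanModel":
        profile = LineScanProfile(
            np.asarray(frame[position], dtype=float),
            np.asarray(frame[red], dtype=float),
            np.asarray(frame[green], dtype=float),
        )
        return cls(profile, **kwargs)

    def fit(self) -> LineScanResults:
        scaled = scale_to_basal(self.profile, self.basal_percentile,
                                self.basal_method)
        # analysis runs on the unclipped basal-subtracted trace so baseline
        # noise stays symmetric; `scaled` (clipped) is retained for audit
        basal = {
            name: (0.0 if np.all(chan == 0)
                   else estimate_basal(chan, self.basal_percentile,
                                       self.basal_method))
            for name, chan in (("red", self.profile.red),
                               ("green", self.profile.green))
        }
        analysis = self.profile.with_channels(
            self.profile.red - basal["red"],
            self.profile.green - basal["green"], scaled.flags,
        )
        smoothed = smooth(analysis, self.filter_settings)
        (lpos, _), (rpos, _) = find_two_peaks(
            smoothed.position, smoothed.red, self.min_separation
        )
        # split the span at the midpoint between the peaks: one window per
        # peak.  Peak *localisation* uses the smoothed trace; the Gaussian
        # fits and the areas use the unsmoothed basal-corrected trace, whose
        # white residuals keep the BIC penalty honest (filtfilt correlates
        # neighbouring samples, which would overstate the evidence for the
        # two-component model) and whose areas suffer no filter-induced mass
        # redistribution across segment boundaries.
        mid = 0.5 * (lpos + rpos)
        lo, hi = smoothed.span
        x = analysis.position
        left_fit = fit_peak(x, analysis.red, (lo, mid), self.bic_margin)
        right_fit = fit_peak(x, analysis.red, (mid, hi), self.bic_margin)
        points = segment_points(left_fit, right_fit, span=(lo, hi))
        red_raw, green_raw = analysis.red, analysis.green
        residual = {"red": 0.0, "green": 0.0}
        if self.refine_background:
            # exterior of the BM windows (with a 2-sigma buffer) carries no
            # structure in either channel; its mean is the residual
            # background left by the first-pass basal estimate
            exterior = (x < points.s1 - 2 * left_fit.effective_sd) | (
                x > points.s4 + 2 * right_fit.effective_sd
            )
            if int(exterior.sum()) >= 16:
                residual["red"] = float(np.mean(red_raw[exterior]))
                residual["green"] = float(np.mean(green_raw[exterior]))
                red_raw = red_raw - residual["red"]
                green_raw = green_raw - residual["green"]
                # second pass: refit the red peaks on the refined trace
                left_fit = fit_peak(x, red_raw, (lo, mid), self.bic_margin)
                right_fit = fit_peak(x, red_raw, (mid, hi), self.bic_margin)
                points = segment_points(left_fit, right_fit, span=(lo, hi))
        smoothed = smoothed.with_channels(smoothed.red - residual["red"],
                                          smoothed.green - residual["green"])
        red_ab = region_abundance(x, red_raw, points)
        green_ab = region_abundance(x, green_raw, points)
        ratio = stoichiometry(red_ab, green_ab, self.stoichiometry_convention)
        params = {
            "basal_percentile": self.basal_percentile,
            "basal_method": self.basal_method,
            "filter_order": self.filter_settings.filter_order,
            "cutoff_fraction": self.filter_settings.cutoff_fraction,
            "min_separation_um": self.min_separation,
            "bic_margin": self.bic_margin,
            "refine_background": self.refine_background,
            "basal_estimate": basal,
            "residual_background": residual,
            "stoichiometry_convention": self.stoichiometry_convention,
        }
        return LineScanResults(
            self.profile, scaled, smoothed, left_fit, right_fit, points,
            red_ab, green_ab, ratio, params,
        )


def analyze_linescan(profile: LineScanProfile, **kwargs) -> LineScanResults:
    """Convenience wrapper: LineScanModel(profile, **kwargs).fit()."""
    return LineScanModel(profile, **kwargs).fit()


def sample_regions(candidates: Sequence, n: int, seed) -> list:
    """Uniform seeded subsample without replacement, preserving input order.

    Mirrors the random selection of endomysial regions per image used when a
    whole image yields more candidate line scans than are quantified.
    """
    candidates = list(candidates)
    if n > len(candidates):
        raise ValueError(
            f"requested {n} regions but only {len(candidates)} candidates"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]
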