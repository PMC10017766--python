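"""Synthetic data generators with exact stored ground truth.

Every input class the analysis pipeline consumes can be generated here with
known truth, so every downstream stage is testable without microscopy or AFM
hardware:

* two-channel endomysial line profiles — two Gaussian basement-membrane (BM)
  peaks over a baseline in the red (laminin alpha-2) channel; the green
  channel carries a configurable fraction of the BM peaks plus a plateau on
  the interstitial-matrix (IM) interval, so BM/IM abundances have closed
  forms;
* per-location peak-intensity fields for remodeling-index recovery;
* persistent-random-walk cell tracks at a fixed 10-min imaging interval;
* fields of myotubes (>= 3 nuclei), myocytes (1-2 nuclei) and mononuclear
  cells as non-overlapping axis-aligned ellipses;
* Hertzian (conical-tip) force curves with an adhesion dip on retraction.

Noise models are additive Gaussian for intensity traces and forces, and
multiplicative lognormal for per-location intensity variation — the simplest
models consistent with fluorescence and AFM practice.  All generators are
pure functions of (parameters, seed); seeds are explicit arguments, never
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .afm import ForceCurve, TipModel, hertz_coefficient
from .linescan import (
    LineScanProfile,
    SegmentPoints,
    gaussian,
    gaussian_window_integral,
)
from .motility import EllipseRegion, FusionField, TrackSet

__all__ = [
    "LineScanTruth",
    "generate_linescan",
    "RemodelingField",
    "generate_remodeling_field",
    "TrackTruth",
    "SimulatedTracks",
    "generate_tracks",
    "FusionFieldTruth",
    "SimulatedFusionField",
    "generate_fusion_field",
    "rasterize_fusion_field",
    "ForceCurveTruth",
    "generate_force_curve",
]


# ---------------------------------------------------------------------------
# line scans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineScanTruth:
    """Generative parameters of one synthetic endomysial line scan.

    Defaults describe a 20-um span sampled at 0.05 um with two well-separated
    BM peaks, a green channel carrying 80% of the BM signal plus an IM
    plateau, and noise at one twentieth of the main peak amplitude — a
    typical signal-to-noise ratio for confocal profiles of bright
    immunostained ECM.
    """

    peak1_center: float = 6.0      # um
    peak1_sd: float = 1.0          # um
    peak1_amplitude: float = 100.0
    peak2_center: float = 14.0     # um
    peak2_sd: float = 1.0          # um
    peak2_amplitude: float = 90.0
    baseline: float = 20.0
    green_bm_fraction: float = 0.8   # in [0, 1]
    green_im_level: float = 50.0
    green_im_edge_um: float = 0.4    # erf edge width of the IM plateau
    noise_sd: float = 5.0
    spacing: float = 0.05          # um/sample
    n_samples: int = 401
    seed: int = 0

    def __post_init__(self):
        if self.peak1_center + 2 * self.peak1_sd >= self.peak2_center - 2 * self.peak2_sd:
            raise ValueError(
                "BM peak windows overlap: peak1_center + 2*sd must lie left of "
                "peak2_center - 2*sd — narrow the peaks or separate the centers"
            )
        span_hi = self.spacing * (self.n_samples - 1)
        if (self.peak1_center - 2 * self.peak1_sd < 0
                or self.peak2_center + 2 * self.peak2_sd > span_hi):
            raise ValueError("peaks (mean +- 2 sd) must lie inside the span")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peak1_amplitude <= 0 or self.peak2_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if not 0 <= self.green_bm_fraction <= 1:
            raise ValueError("green_bm_fraction must lie in [0, 1]")

    # -- closed-form ground truth -------------------------------------------

    @property
    def position(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.spacing

    def true_segment_points(self) -> SegmentPoints:
        return SegmentPoints(
            self.peak1_center - 2 * self.peak1_sd,
            self.peak1_center + 2 * self.peak1_sd,
            self.peak2_center - 2 * self.peak2_sd,
            self.peak2_center + 2 * self.peak2_sd,
        )

    def red_noiseless(self, x: np.ndarray) -> np.ndarray:
        return (
            self.baseline
            + gaussian(x, self.peak1_amplitude, self.peak1_center, self.peak1_sd)
            + gaussian(x, self.peak2_amplitude, self.peak2_center, self.peak2_sd)
        )

    def _im_shape(self, x) -> np.ndarray:
        """IM plateau between the BM windows with smooth erf-shaped edges
        (interstitial components fade into the basement membrane rather
        than cutting off discontinuously)."""
        from scipy.special import ndtr

        x = np.asarray(x, dtype=float)
        pts = self.true_segment_points()
        w = self.green_im_edge_um
        if w <= 0:
            return np.where((x > pts.s2) & (x < pts.s3),
                            self.green_im_level, 0.0)
        return self.green_im_level * (
            ndtr((x - pts.s2) / w) - ndtr((x - pts.s3) / w)
        )

    def _im_shape_integral(self, lo: float, hi: float) -> float:
        """Closed-form integral of the IM plateau shape over [lo, hi]."""
        pts = self.true_segment_points()
        w = self.green_im_edge_um
        if w <= 0:
            return self.green_im_level * max(
                0.0, min(hi, pts.s3) - max(lo, pts.s2))

        def antideriv(x: float) -> float:
            # integral of Phi((x-a)/w) is w*(u*Phi(u) + phi(u)), u=(x-a)/w
            total = 0.0
            for a, sign in ((pts.s2, 1.0), (pts.s3, -1.0)):
                u = (x - a) / w
                phi = math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
                Phi = 0.5 * (1.0 + math.erf(u / math.sqrt(2.0)))
                total += sign * w * (u * Phi + phi)
            return total

        return self.green_im_level * (antideriv(hi) - antideriv(lo))

    def green_noiseless(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        bm = self.green_bm_fraction * (
            gaussian(x, self.peak1_amplitude, self.peak1_center, self.peak1_sd)
            + gaussian(x, self.peak2_amplitude, self.peak2_center, self.peak2_sd)
        )
        return self.baseline + bm + self._im_shape(x)

    def _red_peak_integral(self, lo: float, hi: float) -> float:
        """Baseline-free red signal integrated over [lo, hi] (closed form)."""
        return gaussian_window_integral(
            self.peak1_amplitude, self.peak1_sd, lo, hi, self.peak1_center
        ) + gaussian_window_integral(
            self.peak2_amplitude, self.peak2_sd, lo, hi, self.peak2_center
        )

    def true_red_abundance(self) -> dict:
        pts = self.true_segment_points()
        return {
            "bm_left": self._red_peak_integral(pts.s1, pts.s2),
            "im": self._red_peak_integral(pts.s2, pts.s3),
            "bm_right": self._red_peak_integral(pts.s3, pts.s4),
        }

    def true_green_abundance(self) -> dict:
        pts = self.true_segment_points()
        f = self.green_bm_fraction
        return {
            "bm_left": f * self._red_peak_integral(pts.s1, pts.s2)
                       + self._im_shape_integral(pts.s1, pts.s2),
            "im": f * self._red_peak_integral(pts.s2, pts.s3)
                  + self._im_shape_integral(pts.s2, pts.s3),
            "bm_right": f * self._red_peak_integral(pts.s3, pts.s4)
                        + self._im_shape_integral(pts.s3, pts.s4),
        }


def generate_linescan(truth: LineScanTruth) -> tuple[LineScanProfile, LineScanTruth]:
    """Sample one noisy two-channel profile from its generative truth."""
    rng = np.random.default_rng(truth.seed)
    x = truth.position
    red = truth.red_noiseless(x) + rng.normal(0.0, truth.noise_sd, x.size)
    green = truth.green_noiseless(x) + rng.normal(0.0, truth.noise_sd, x.size)
    profile = LineScanProfile(x, np.clip(red, 0.0, None),
                              np.clip(green, 0.0, None))
    return profile, truth


# ---------------------------------------------------------------------------
# remodeling fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemodelingField:
    """Control/treated peak intensities with the exact per-location ratios.

    The per-location remodeling ratio is drawn lognormal with mean equal to
    ``remodeling_factor`` and coefficient of variation ``cv``; the treated
    intensity is control_mean / ratio.  Placing the noise on the ratio keeps
    the stored ratios — and the downstream RI — unbiased for the factor.
    """

    control: np.ndarray
    treated: np.ndarray
    true_ratios: np.ndarray
    control_mean: float
    remodeling_factor: float
    cv: float
    seed: int


def _lognormal_mean1(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), size)


def generate_remodeling_field(
    control_mean: float,
    remodeling_factor: float,
    cv: float,
    n_locations: int,
    seed: int,
) -> RemodelingField:
    """Simulate per-location peak intensities for both conditions."""
    if remodeling_factor < 1:
        raise ValueError("remodeling_factor must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    rng = np.random.default_rng(seed)
    control = control_mean * _lognormal_mean1(rng, cv, n_locations)
    ratios = remodeling_factor * _lognormal_mean1(rng, cv, n_locations)
    treated = control_mean / ratios
    return RemodelingField(control, treated, ratios, control_mean,
                           remodeling_factor, cv, seed)


# ---------------------------------------------------------------------------
# cell tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackTruth:
    """Persistent-random-walk parameters for a cohort of cells.

    Defaults mirror the live-imaging design: 10-min interval, a 15-h window
    (91 frames = 90 intervals), speeds around 6 um per interval.
    """

    n_cells: int = 20
    frames: int = 91
    interval: float = 10.0       # minutes
    speed_mean: float = 6.2      # um per interval
    speed_sd: float = 1.5        # um per interval
    persistence: float = 0.6     # 1 = straight-line motion
    dropout_rate: float = 0.0    # probability a track is truncated
    seed: int = 0

    def __post_init__(self):
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must lie in [0, 1]")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")


@dataclass
class SimulatedTracks:
    tracks: TrackSet
    true_step_lengths: dict = field(default_factory=dict)  # cell_id -> array


def generate_tracks(truth: TrackTruth) -> SimulatedTracks:
    """Persistent random walks with per-interval step lengths stored as truth."""
    import pandas as pd

    rng = np.random.default_rng(truth.seed)
    rows = []
    step_truth = {}
    for cid in range(truth.n_cells):
        n_frames = truth.frames
        if truth.dropout_rate > 0 and rng.random() < truth.dropout_rate:
            n_frames = int(rng.integers(2, truth.frames))
        x, y = rng.uniform(0, 500, 2)
        theta = rng.uniform(-math.pi, math.pi)
        steps = np.clip(
            rng.normal(truth.speed_mean, truth.speed_sd, n_frames - 1), 0.0, None
        ) if truth.speed_sd > 0 else np.full(n_frames - 1, truth.speed_mean)
        rows.append({"cell_id": cid, "frame": 0, "x": x, "y": y})
        for k, step in enumerate(steps):
            theta += (1.0 - truth.persistence) * rng.uniform(-math.pi, math.pi)
            x += step * math.cos(theta)
            y += step * math.sin(theta)
            rows.append({"cell_id": cid, "frame": k + 1, "x": x, "y": y})
        step_truth[cid] = steps
    tracks = TrackSet(pd.DataFrame(rows), truth.interval)
    return SimulatedTracks(tracks, step_truth)


# ---------------------------------------------------------------------------
# fusion fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionFieldTruth:
    """Parameters of a synthetic differentiation field.

    Myotubes are elongated ellipses holding at least three nuclei
    (3 + Poisson(extra_nuclei_mean) each); myocytes are small ellipses with
    one or two nuclei; remaining nuclei are mononuclear background cells.
    """

    n_myotubes: int = 6
    extra_nuclei_mean: float = 4.0   # myotube nuclei = 3 + Poisson(this)
    n_myocytes: int = 4
    n_mononuclear: int = 30
    field_size: tuple[float, float] = (400.0, 400.0)  # um
    seed: int = 0

    def __post_init__(self):
        if min(self.n_myotubes, self.n_myocytes, self.n_mononuclear) < 0:
            raise ValueError("counts must be >= 0")
        if self.extra_nuclei_mean < 0:
            raise ValueError("extra_nuclei_mean must be >= 0")


@dataclass
class SimulatedFusionField:
    field: FusionField
    true_index_percent: float
    nuclei_per_region: dict  # label -> count
    truth: FusionFieldTruth


def _place_regions(rng, truth: FusionFieldTruth):
    """Place non-overlapping ellipses by bounded reject-and-retry."""
    w, h = truth.field_size
    placed: list[EllipseRegion] = []
    specs = [("myotube", rng.uniform(20, 40), rng.uniform(6, 12))
             for _ in range(truth.n_myotubes)]
    specs += [("myocyte", rng.uniform(8, 14), rng.uniform(5, 9))
              for _ in range(truth.n_myocytes)]
    label = 0
    regions = []
    too_small = ValueError(
        "field too small to place requested regions without overlap"
    )
    for kind, a, b in specs:
        if w <= 2 * a or h <= 2 * b:
            raise too_small
        r = math.hypot(a, b)
        for _ in range(500):
            cx, cy = rng.uniform(a, w - a), rng.uniform(b, h - b)
            # conservative bounding-circle separation test
            if all(
                math.hypot(cx - p.cx, cy - p.cy)
                > r + math.hypot(p.semi_x, p.semi_y)
                for p in placed
            ):
                label += 1
                region = EllipseRegion(cx, cy, a, b, label)
                placed.append(region)
                regions.append((kind, region))
                break
        else:
            raise too_small
    return regions


def _points_in_ellipse(rng, region: EllipseRegion, n: int) -> np.ndarray:
    # uniform in the unit disc, stretched to the ellipse; margin keeps
    # nuclei strictly interior so membership is unambiguous
    r = 0.9 * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * math.pi, n)
    return np.column_stack([
        region.cx + region.semi_x * r * np.cos(phi),
        region.cy + region.semi_y * r * np.sin(phi),
    ])


def generate_fusion_field(truth: FusionFieldTruth) -> SimulatedFusionField:
    """Simulate a field of myotubes, myocytes and mononuclear cells."""
    rng = np.random.default_rng(truth.seed)
    regions = _place_regions(rng, truth)
    nuclei = []
    per_region = {}
    n_in_myotubes = 0
    for kind, region in regions:
        if kind == "myotube":
            count = 3 + int(rng.poisson(truth.extra_nuclei_mean))
            n_in_myotubes += count
        else:
            count = int(rng.integers(1, 3))  # 1 or 2
        per_region[region.label] = count
        nuclei.append(_points_in_ellipse(rng, region, count))
    ellipses = [region for _, region in regions]
    w, h = truth.field_size
    free = []
    while len(free) < truth.n_mononuclear:
        pt = rng.uniform((0, 0), (w, h))
        if not any(e.contains(pt[0], pt[1]) for e in ellipses):
            free.append(pt)
    if free:
        nuclei.append(np.asarray(free))
    all_nuclei = (np.concatenate(nuclei) if nuclei
                  else np.empty((0, 2)))
    total = len(all_nuclei)
    index = 100.0 * n_in_myotubes / total if total else 0.0
    ffield = FusionField(all_nuclei, tuple(ellipses))
    return SimulatedFusionField(ffield, index, per_region, truth)


def rasterize_fusion_field(
    field: FusionField,
    field_size: tuple[float, float],
    um_per_px: float = 1.0,
) -> np.ndarray:
    """Render the ellipse regions as an integer label mask (image code path)."""
    from skimage.draw import ellipse as draw_ellipse

    w, h = field_size
    mask = np.zeros((int(round(h / um_per_px)), int(round(w / um_per_px))),
                    dtype=np.int32)
    for region in field.regions:
        rr, cc = draw_ellipse(
            region.cy / um_per_px, region.cx / um_per_px,
            region.semi_y / um_per_px, region.semi_x / um_per_px,
            shape=mask.shape,
        )
        mask[rr, cc] = region.label
    return mask


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForceCurveTruth:
    """Generative parameters of one AFM force-separation cycle.

    Defaults mirror a soft-ECM acquisition: conical 35-degree tip,
    incompressible sample, 3 nN trigger force, 2 um/s ramps.
    """

    young_modulus_pa: float = 8000.0
    tip_half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5
    contact_point_um: float = 0.0
    trigger_force_nn: float = 3.0
    adhesion_depth_nn: float = 1.0
    noise_sd_nn: float = 0.02
    approach_speed_um_s: float = 2.0
    baseline_span_um: float = 1.5
    n_samples: int = 600
    seed: int = 0

    def __post_init__(self):
        if self.young_modulus_pa <= 0:
            raise ValueError("young_modulus must be positive")
        if self.trigger_force_nn <= 0:
            raise ValueError("trigger_force must be positive")
        if self.adhesion_depth_nn < 0:
            raise ValueError("adhesion_depth must be >= 0")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")

    @property
    def tip(self) -> TipModel:
        return TipModel("cone", self.tip_half_angle_deg, self.poisson_ratio)

    @property
    def modulus_kpa(self) -> float:
        return self.young_modulus_pa / 1e3

    @property
    def max_indentation_um(self) -> float:
        """Indentation depth at which the noiseless force hits the trigger."""
        coef = hertz_coefficient(self.tip)
        return math.sqrt(self.trigger_force_nn / (coef * self.modulus_kpa))

    def _metadata(self) -> dict:
        return {
            "trigger_force_nN": self.trigger_force_nn,
            "speed_um_s": self.approach_speed_um_s,
            "spring_constant_N_m": 0.02,
        }


def generate_force_curve(
    truth: ForceCurveTruth,
) -> tuple[ForceCurve, ForceCurve, ForceCurveTruth]:
    """Simulate one approach/retraction pair from Hertzian contact truth.

    The approach runs from ``baseline_span_um`` above the contact point down
    to the separation where the noiseless force reaches the trigger force
    (the curve is truncated there, as in acquisition).  The retraction
    retraces the contact region and adds a smooth adhesion dip whose minimum
    equals -adhesion_depth before returning to the free baseline.
    """
    coef = hertz_coefficient(truth.tip)
    e_kpa = truth.modulus_kpa
    s_contact = truth.contact_point_um
    s_start = s_contact + truth.baseline_span_um
    s_end = s_contact - truth.max_indentation_um
    rng = np.random.default_rng(truth.seed)

    sep_app = np.linspace(s_start, s_end, truth.n_samples)
    delta = np.clip(s_contact - sep_app, 0.0, None)
    f_app = coef * e_kpa * delta**2
    f_app_noisy = f_app + rng.normal(0.0, truth.noise_sd_nn, sep_app.size)
    approach = ForceCurve("approach", sep_app, f_app_noisy, truth._metadata())

    sep_ret = sep_app[::-1].copy()
    delta_ret = np.clip(s_contact - sep_ret, 0.0, None)
    f_ret = coef * e_kpa * delta_ret**2
    if truth.adhesion_depth_nn > 0:
        # Gaussian-shaped dip just past contact, normalised on the sampled
        # grid so the noiseless retraction minimum is exactly -adhesion_depth
        beyond = np.clip(sep_ret - s_contact, 0.0, None)
        shape = np.where(
            sep_ret > s_contact,
            np.exp(-((beyond - 0.15) ** 2) / (2 * 0.08**2)),
            0.0,
        )
        peak = float(np.max(shape))
        if peak > 0:
            f_ret = f_ret - truth.adhesion_depth_nn * shape / peak
    f_ret_noisy = f_ret + rng.normal(0.0, truth.noise_sd_nn, sep_ret.size)
    retract = ForceCurve("retract", sep_ret, f_ret_noisy, truth._metadata())
    return approach, retract, truth
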