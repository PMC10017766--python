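"""Tabular readers/writers, run configuration, and the pipeline driver.

All machine outputs are deterministic for a fixed config and seed: floats
are written at full double precision with a fixed format, JSON keys are
sorted, and no timestamps are embedded — rerunning a pipeline reproduces the
output files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afm as afm_mod
from . import linescan as ls
from . import motility as mot
from . import remodeling as rem
from . import synthetic as syn

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_intensity_csv",
    "write_intensity_csv",
    "read_force_curve_csv",
    "write_force_curve_csv",
    "write_json",
    "RunConfig",
    "run_pipeline",
]

FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    """Delimited text with auto-detected comma/tab separator and an optional
    header row (ImageJ plot-profile exports come both ways)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    first = df.iloc[0]
    try:
        first.astype(float)
        return df
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
        df.columns = [str(v) for v in first]
        return df


def read_profile_csv(
    path,
    column_map: dict | None = None,
    calibration_um_per_px: float | None = None,
) -> ls.LineScanProfile:
    """Read an ImageJ-style plot-profile export into a LineScanProfile.

    column_map maps {"position", "red", "green"} to column labels or integer
    positions; by default the first three columns are taken in that order
    (two-column files are read as red-only, green set to zero and flagged).
    If positions are in pixels, pass calibration_um_per_px to convert.
    """
    df = _read_table(path)

    def col(key, default_idx):
        if column_map and key in column_map:
            sel = column_map[key]
            series = df.iloc[:, sel] if isinstance(sel, int) else df[sel]
        else:
            if default_idx >= df.shape[1]:
                return None
            series = df.iloc[:, default_idx]
        return series.astype(float).to_numpy()

    position = col("position", 0)
    red = col("red", 1)
    green = col("green", 2)
    flags = ()
    if red is None or position is None:
        raise ValueError(f"{path}: need at least two numeric columns")
    if green is None:
        green = np.zeros_like(red)
        flags = ("green_channel_missing",)
    if calibration_um_per_px is not None:
        position = position * calibration_um_per_px
    return ls.LineScanProfile(position, red, green, flags)


def write_profile_csv(profile: ls.LineScanProfile, path) -> None:
    pd.DataFrame({
        "position_um": profile.position,
        "red": profile.red,
        "green": profile.green,
    }).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

_IMARIS_COLUMNS = {"cell_id": "TrackID", "frame": "Time",
                   "x": "PositionX", "y": "PositionY"}


def read_tracks_csv(
    path,
    column_map: dict | None = None,
    interval_minutes: float = mot.DEFAULT_INTERVAL_MIN,
) -> mot.TrackSet:
    """Read an Imaris-style track export into a TrackSet.

    column_map maps {"cell_id", "frame", "x", "y"} to the file's column
    labels; plain lower-case names and the Imaris TrackID/Time/PositionX/
    PositionY convention are recognised automatically.  Rows are canonically
    sorted, so shuffled exports parse identically.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for key in ("cell_id", "frame", "x", "y"):
        if column_map and key in column_map:
            rename[column_map[key]] = key
        elif key in df.columns:
            pass
        elif _IMARIS_COLUMNS[key] in df.columns:
            rename[_IMARIS_COLUMNS[key]] = key
        else:
            raise ValueError(f"{path}: cannot locate column for {key!r}")
    df = df.rename(columns=rename)[["cell_id", "frame", "x", "y"]]
    df["frame"] = df["frame"].astype(int)
    return mot.TrackSet(df, interval_minutes)


def write_tracks_csv(tracks: mot.TrackSet, path) -> None:
    tracks.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# intensity sets (remodeling)
# ---------------------------------------------------------------------------


def read_intensity_csv(path) -> dict[str, rem.IntensitySet]:
    """Long-format peak intensities: sample_id, condition, location_id,
    peak_intensity.  Returns one IntensitySet per condition."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"condition", "location_id", "peak_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for condition, grp in df.groupby("condition"):
        out[str(condition)] = rem.IntensitySet(
            str(condition),
            grp["peak_intensity"].to_numpy(dtype=float),
            tuple(grp["location_id"]),
        )
    return out


def write_intensity_csv(sets: dict[str, rem.IntensitySet], path,
                        sample_id: str = "sim") -> None:
    rows = []
    for condition, iset in sets.items():
        ids = iset.location_ids or range(iset.n)
        for loc, val in zip(ids, iset.intensities):
            rows.append({"sample_id": sample_id, "condition": condition,
                         "location_id": loc, "peak_intensity": val})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------


def write_force_curve_csv(curve: afm_mod.ForceCurve, path) -> None:
    """Two-column CSV with a small '#'-prefixed metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# segment={curve.segment}\n")
        for key in sorted(curve.metadata):
            fh.write(f"# {key}={curve.metadata[key]}\n")
        fh.write("separation_um,force_nN\n")
        for s, f in zip(curve.separation, curve.force):
            fh.write(f"{s:.12g},{f:.12g}\n")


def read_force_curve_csv(path) -> afm_mod.ForceCurve:
    meta = {}
    segment = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            key = key.strip()
            if key == "segment":
                segment = value.strip()
            else:
                try:
                    meta[key] = float(value)
                except ValueError:
                    meta[key] = value.strip()
    if segment is None:
        raise ValueError(f"{path}: missing '# segment=' metadata line")
    df = pd.read_csv(path, comment="#")
    return afm_mod.ForceCurve(
        segment, df["separation_um"].to_numpy(dtype=float),
        df["force_nN"].to_numpy(dtype=float), meta,
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration and pipeline driver
# ---------------------------------------------------------------------------

ALL_STAGES = ("linescan", "remodel", "motility", "fusion", "afm")


@dataclass
class RunConfig:
    """Single structured configuration for the simulate-and-analyze pipeline.

    Every algorithm parameter is recorded in the output bundle together with
    the seed, so each result row is traceable to its inputs.
    """

    outdir: str = "results"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # linescan
    n_profiles: int = 20
    basal_percentile: float = 5.0
    basal_method: str = "clipped_mean"
    filter_order: int = 3
    cutoff_fraction: float = 0.2
    min_separation_um: float | None = None
    bic_margin: float = 2.0
    linescan_truth: dict = field(default_factory=dict)
    # remodel
    remodeling_factor: float = 5.4
    remodeling_cv: float = 0.2
    n_locations: int = 20
    control_mean: float = 100.0
    # motility
    track_truth: dict = field(default_factory=dict)
    window_minutes: tuple | None = None
    displacement_minutes: float = 900.0
    # fusion
    n_fields: int = 5
    fusion_truth: dict = field(default_factory=dict)
    # afm
    n_curves: int = 20
    force_truth: dict = field(default_factory=dict)
    tip_geometry: str = "cone"
    tip_half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.basal_percentile < 100:
            raise ValueError("basal_percentile must lie in (0, 100)")
        if not 0 < self.cutoff_fraction < 1:
            raise ValueError("cutoff_fraction must lie in (0, 1)")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.bic_margin < 0:
            raise ValueError("bic_margin must be >= 0")
        if self.remodeling_factor < 1:
            raise ValueError("remodeling_factor must be >= 1")
        if self.remodeling_cv < 0:
            raise ValueError("remodeling_cv must be >= 0")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if min(self.n_profiles, self.n_locations, self.n_fields,
               self.n_curves) < 1:
            raise ValueError("per-stage sample counts must be >= 1")


def _stage_linescan(cfg: RunConfig, seed: int, outdir: Path, log: list) -> None:
    rows = []
    details = {}
    n_rejected = 0
    for i in range(cfg.n_profiles):
        truth = syn.LineScanTruth(seed=seed + i, **cfg.linescan_truth)
        profile, _ = syn.generate_linescan(truth)
        model = ls.LineScanModel(
            profile,
            basal_percentile=cfg.basal_percentile,
            basal_method=cfg.basal_method,
            filter_settings=ls.FilterSettings(cfg.filter_order,
                                              cfg.cutoff_fraction),
            min_separation=cfg.min_separation_um,
            bic_margin=cfg.bic_margin,
        )
        try:
            res = model.fit()
        except ls.NoDistinctPeaksError as exc:
            n_rejected += 1
            log.append(f"linescan: profile_{i:03d} excluded: {exc}")
            continue
        pid = f"profile_{i:03d}"
        details[pid] = res.to_dict()
        for channel, ab in (("red", res.red_abundance),
                            ("green", res.green_abundance)):
            for region, value in (("bm_left", ab.bm_left), ("im", ab.im),
                                  ("bm_right", ab.bm_right)):
                rows.append({
                    "profile_id": pid, "region": region, "channel": channel,
                    "abundance_I_um": value,
                    "peak_intensity": ab.peak_bm_intensity,
                    "flags": ";".join(res.flags),
                })
    pd.DataFrame(rows).to_csv(outdir / "linescan_results.csv", index=False,
                              float_format=FLOAT_FORMAT)
    write_json(details, outdir / "linescan_results.json")
    log.append(f"linescan: analyzed {len(details)} profiles, "
               f"rejected {n_rejected} (no distinct basement membrane)")


def _stage_remodel(cfg: RunConfig, seed: int, outdir: Path, log: list) -> None:
    fld = syn.generate_remodeling_field(
        cfg.control_mean, cfg.remodeling_factor, cfg.remodeling_cv,
        cfg.n_locations, seed,
    )
    control = rem.IntensitySet("myoscaffold", fld.control)
    treated = rem.IntensitySet("myoscaffold + cells", fld.treated)
    write_intensity_csv({"myoscaffold": control,
                         "myoscaffold + cells": treated},
                        outdir / "remodel_intensities.csv")
    result = rem.remodeling_index(control, treated)
    pd.DataFrame([{
        "mean_ri": result.mean_ri, "sd_ri": result.sd_ri,
        "n_locations": result.n_locations,
        "true_factor": cfg.remodeling_factor,
    }]).to_csv(outdir / "remodel_summary.csv", index=False,
               float_format=FLOAT_FORMAT)
    log.append(f"remodel: {result.summary()}")


def _stage_motility(cfg: RunConfig, seed: int, outdir: Path, log: list) -> None:
    sim = syn.generate_tracks(syn.TrackTruth(seed=seed, **cfg.track_truth))
    tracks = sim.tracks
    write_tracks_csv(tracks, outdir / "tracks.csv")
    summary = mot.mean_speed(tracks, cfg.window_minutes)
    disp_rows = []
    n_incomplete = 0
    for cid in tracks.cell_ids:
        try:
            d = mot.total_displacement(tracks, cid, cfg.displacement_minutes)
        except mot.IncompleteTrackError as exc:
            n_incomplete += 1
            log.append(f"motility: {exc}")
            continue
        disp_rows.append({
            "cell_id": cid, "path_length_um": d.path_length_um,
            "net_displacement_um": d.net_displacement_um,
            "n_intervals": d.n_intervals,
        })
    summary.per_cell.merge(
        pd.DataFrame(disp_rows,
                     columns=["cell_id", "path_length_um",
                              "net_displacement_um", "n_intervals"]),
        on="cell_id", how="left",
    ).to_csv(outdir / "motility_per_cell.csv", index=False,
             float_format=FLOAT_FORMAT)
    log.append(f"motility: {summary.summary()}; "
               f"{n_incomplete} incomplete tracks excluded from displacement")


def _stage_fusion(cfg: RunConfig, seed: int, outdir: Path, log: list) -> None:
    rows = []
    for i in range(cfg.n_fields):
        sim = syn.generate_fusion_field(
            syn.FusionFieldTruth(seed=seed + i, **cfg.fusion_truth))
        res = mot.fusion_efficiency(sim.field)
        rows.append({
            "field_id": f"field_{i:03d}",
            "fusion_efficiency_percent": res.efficiency_percent,
            "true_index_percent": sim.true_index_percent,
            "n_nuclei": res.n_nuclei,
            "n_in_myotubes": res.n_in_myotubes,
        })
    pd.DataFrame(rows).to_csv(outdir / "fusion.csv", index=False,
                              float_format=FLOAT_FORMAT)
    log.append(f"fusion: scored {len(rows)} fields")


def _stage_afm(cfg: RunConfig, seed: int, outdir: Path, log: list) -> None:
    tip = afm_mod.TipModel(cfg.tip_geometry, cfg.tip_half_angle_deg,
                           cfg.poisson_ratio)
    results = []
    for i in range(cfg.n_curves):
        approach, retract, _ = syn.generate_force_curve(
            syn.ForceCurveTruth(seed=seed + i, **cfg.force_truth))
        res = afm_mod.HertzSneddonModel(approach, retract, tip).fit()
        res.group = "simulated"
        results.append(res)
    per_curve = pd.DataFrame({
        "curve_id": [f"curve_{i:03d}" for i in range(len(results))],
        "young_modulus_kpa": [r.young_modulus_kpa for r in results],
        "rupture_force_nn": [r.rupture_force_nn for r in results],
        "contact_point_um": [r.contact_point_um for r in results],
    })
    per_curve.to_csv(outdir / "afm_per_curve.csv", index=False,
                     float_format=FLOAT_FORMAT)
    afm_mod.batch_summary(results).to_csv(
        outdir / "afm_summary.csv", index=False, float_format=FLOAT_FORMAT)
    log.append(f"afm: fitted {len(results)} curves")


_STAGE_FUNCS = {
    "linescan": _stage_linescan,
    "remodel": _stage_remodel,
    "motility": _stage_motility,
    "fusion": _stage_fusion,
    "afm": _stage_afm,
}


def run_pipeline(config: RunConfig) -> dict:
    """Simulate inputs and run every requested analysis stage.

    Writes result CSV/JSON files, a parameter echo (params.json, embedding
    the full configuration and seed) and a plain-text log recording
    per-stage counts and every exclusion with its reason.  Deterministic:
    identical config + seed reproduces identical bytes.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"pipeline seed={config.seed} stages={list(config.stages)}"]
    # disjoint seed offsets per stage keep stages independent of stage order
    offsets = {name: 10_000 * (k + 1) for k, name in enumerate(ALL_STAGES)}
    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, config.seed + offsets[stage], outdir, log)
        except Exception as exc:
            log.append(f"{stage}: FAILED: {exc}")
            (outdir / "pipeline_log.txt").write_text("\n".join(log) + "\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    write_json(asdict(config) | {"stage_seed_offsets": offsets},
               outdir / "params.json")
    (outdir / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return {"outdir": str(outdir), "log": log}
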