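"""End-to-end orchestration and experiment-vs-theory comparison.

``run_pipeline`` composes the full workflow — simulate (or ingest) →
detect/track (or ingest tracks) → drift-correct → MSD → alpha and D →
hydrodynamic prediction → comparison — and persists every intermediate to a
report bundle directory (``config.yaml``, ``tracks.csv``,
``tracks_corrected.csv``, ``msd.csv``, ``summary.json``,
``comparison.csv``).  A run is reproducible from its config alone: the
bundle is byte-stable for a fixed config + seed, and every output carries
the config hash.

``compare`` joins measured and predicted diffusivities on surface
concentration and reports the ratio and its log10; concentrations where the
two disagree by an order of magnitude or more are flagged as regime
disagreement.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detection_tracking, hydrodynamics, monolayer, msd_analysis
from . import synthetic_data as synth

logger = logging.getLogger("memspt")

GAMMA_JOIN_TOLERANCE = 0.05  # mg/m^2; the experimental Gamma grid step is 0.5


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackingParams:
    """Detection/linking settings (defaults tuned on the synthetic fixtures)."""
    feature_diameter_px: int = 9
    intensity_threshold_pct: float = 99.0
    noise_length_px: float = 1.0
    invert: bool = True
    max_displacement_um: float = 1.0
    memory: int = 0
    min_track_length: int = 10


@dataclass(frozen=True)
class AnalysisParams:
    target_lag_s: float = 1.0
    alpha_window: tuple[float, float] = (0.5, 5.0)
    max_lag_s: float = 10.0
    drift_correct: bool = True
    drift_population: str | None = None  # restrict drift estimation to one class


@dataclass(frozen=True)
class MembraneParams:
    radius_um: float = 5.0
    superphase_viscosity: float = hydrodynamics.AIR_VISCOSITY
    subphase_viscosity: float = hydrodynamics.WATER_VISCOSITY_21C
    temperature: float = 294.0


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``mode``: ``"tracks"`` analyses simulated noisy tracks directly;
    ``"render"`` additionally renders frames and re-detects/links them;
    ``"ingest"`` skips simulation and reads ``tracks_csv``.
    """
    seed: int = 0
    mode: str = "tracks"
    imaging: synth.ImagingConfig = field(default_factory=synth.ImagingConfig)
    populations: list[synth.ParticlePopulation] = field(
        default_factory=synth.default_populations)
    drift: synth.DriftModel = field(default_factory=synth.DriftModel.none)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    gamma_mg_m2: float | None = None       # monolayer condition of this run
    viscosity_table: list[dict] | None = None  # rows: gamma_mg_m2, eta_Pa_s_m
    tracks_csv: str | None = None
    outdir: str = "memspt_run"

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "imaging" in d and isinstance(d["imaging"], dict):
            im = dict(d["imaging"])
            if "image_shape" in im:
                im["image_shape"] = tuple(im["image_shape"])
            d["imaging"] = synth.ImagingConfig(**im)
        if "populations" in d:
            d["populations"] = [synth.ParticlePopulation(**p) if isinstance(p, dict)
                                else p for p in d["populations"]]
        if "drift" in d and isinstance(d["drift"], dict):
            dr = dict(d["drift"])
            if isinstance(dr.get("velocity"), list):
                v = dr["velocity"]
                dr["velocity"] = (tuple(map(tuple, v)) if v and isinstance(v[0], list)
                                  else tuple(v))
            if isinstance(dr.get("segment_bounds"), list):
                dr["segment_bounds"] = tuple(dr["segment_bounds"])
            d["drift"] = synth.DriftModel(**dr)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingParams(**d["tracking"])
        if "analysis" in d and isinstance(d["analysis"], dict):
            an = dict(d["analysis"])
            if isinstance(an.get("alpha_window"), list):
                an["alpha_window"] = tuple(an["alpha_window"])
            d["analysis"] = AnalysisParams(**an)
        if "membrane" in d and isinstance(d["membrane"], dict):
            d["membrane"] = MembraneParams(**d["membrane"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        # outdir is bookkeeping, not part of the scientific run
        d = self.to_dict()
        d.pop("outdir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def compare(experimental: pd.DataFrame, predicted: pd.DataFrame,
            gamma_tolerance: float = GAMMA_JOIN_TOLERANCE) -> pd.DataFrame:
    """Join measured and predicted D on surface concentration.

    ``experimental`` needs columns ``gamma_mg_m2, D_um2_s`` (optionally
    ``D_sd_um2_s``); ``predicted`` is a :func:`~memspt.hydrodynamics.predict_curve`
    table.  Each experimental row is matched to the nearest predicted Gamma
    within ``gamma_tolerance`` mg/m^2.  Output columns: the joined values,
    ``ratio`` = D_exp / D_pred, ``log10_ratio`` and ``regime_disagreement``
    (|log10 ratio| >= 1, i.e. an order of magnitude or more apart).
    Raises if no Gamma overlaps.
    """
    if len(predicted) == 0 or len(experimental) == 0:
        raise ValueError("need non-empty experimental and predicted tables")
    rows = []
    pg = predicted["gamma_mg_m2"].to_numpy(dtype=float)
    for _, row in experimental.iterrows():
        g = float(row["gamma_mg_m2"])
        j = int(np.argmin(np.abs(pg - g)))
        if abs(pg[j] - g) > gamma_tolerance:
            continue
        d_exp = float(row["D_um2_s"])
        d_pred = float(predicted["D_um2_s"].iloc[j])
        ratio = d_exp / d_pred if d_pred > 0 else np.nan
        log10_ratio = np.log10(ratio) if ratio > 0 else np.nan
        rows.append({
            "gamma_mg_m2": g,
            "D_exp_um2_s": d_exp,
            "D_exp_sd_um2_s": float(row.get("D_sd_um2_s", np.nan)),
            "D_pred_um2_s": d_pred,
            "ratio": ratio,
            "log10_ratio": log10_ratio,
            "regime_disagreement": bool(np.isfinite(log10_ratio)
                                        and abs(log10_ratio) >= 1.0),
        })
    if not rows:
        raise ValueError(
            f"no experimental Gamma within {gamma_tolerance} mg/m^2 of a "
            "predicted Gamma")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config`` and write the report
    bundle to ``config.outdir``.  Returns the summary dict.

    Any stage failure raises with the stage name; intermediates produced up
    to that point remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_yaml(outdir / "config.yaml")
    stage = "setup"
    try:
        # --- acquire tracks -------------------------------------------------
        if config.tracks_csv is not None or config.mode == "ingest":
            stage = "ingest"
            _stage(stage)
            if config.tracks_csv is None:
                raise ValueError("mode 'ingest' requires tracks_csv")
            tracks = synth.read_tracks(config.tracks_csv)
        else:
            stage = "simulate"
            _stage(stage)
            truth = synth.simulate_tracks(config.populations, config.imaging,
                                          config.drift, config.seed)
            synth.write_drift_path(truth.drift_path, outdir / "drift_true.csv")
            if config.mode == "render":
                stage = "render"
                _stage(stage)
                stack = synth.render_frames(truth)
                stage = "detect_track"
                _stage(stage)
                tp = config.tracking
                tracks = detection_tracking.track_stack(
                    stack, pixel_size=config.imaging.pixel_size,
                    feature_diameter=tp.feature_diameter_px,
                    intensity_threshold=tp.intensity_threshold_pct,
                    max_displacement=tp.max_displacement_um,
                    min_length=tp.min_track_length, memory=tp.memory,
                    noise_length=tp.noise_length_px, invert=tp.invert)
            elif config.mode == "tracks":
                tracks = truth.noisy_tracks
            else:
                raise ValueError(f"unknown mode {config.mode!r}")
        synth.write_tracks(tracks, outdir / "tracks.csv")

        # --- drift correction ----------------------------------------------
        stage = "drift_correction"
        _stage(stage)
        if config.analysis.drift_correct:
            corrected, drift_est = msd_analysis.correct_drift(
                tracks, frame_rate=config.imaging.frame_rate,
                population=config.analysis.drift_population)
        else:
            corrected, drift_est = tracks, None
        synth.write_tracks(corrected, outdir / "tracks_corrected.csv")

        # --- MSD / alpha / D ------------------------------------------------
        stage = "msd"
        _stage(stage)
        curve = msd_analysis.compute_msd(corrected, config.imaging.frame_rate,
                                         max_lag_s=config.analysis.max_lag_s)
        curve.to_frame().to_csv(outdir / "msd.csv", index=False)
        fit = msd_analysis.fit_alpha(curve, config.analysis.alpha_window)
        d_est = msd_analysis.diffusivity_at_lag(curve,
                                                config.analysis.target_lag_s)

        # --- static-noise floor (immobilized-particle protocol) -------------
        stage = "noise_floor"
        _stage(stage)
        floor_imaging = dataclasses.replace(
            config.imaging, n_frames=min(config.imaging.n_frames, 2000))
        immobile = synth.simulate_immobile(20, floor_imaging,
                                           seed=config.seed + 10_000)
        floor_curve = msd_analysis.compute_msd(
            immobile.noisy_tracks, floor_imaging.frame_rate,
            max_lag_s=min(2.0, floor_imaging.duration / 4))
        floor = msd_analysis.noise_floor(floor_curve)

        # --- theory and comparison ------------------------------------------
        stage = "predict"
        _stage(stage)
        comparison = None
        prediction = None
        if config.viscosity_table:
            visc = pd.DataFrame(config.viscosity_table)
            prediction = hydrodynamics.predict_curve(
                config.membrane.radius_um * 1e-6, visc,
                config.membrane.superphase_viscosity,
                config.membrane.subphase_viscosity,
                config.membrane.temperature)
            prediction.to_csv(outdir / "prediction.csv", index=False)
            if config.gamma_mg_m2 is not None:
                exp_df = pd.DataFrame([{"gamma_mg_m2": config.gamma_mg_m2,
                                        "D_um2_s": d_est.D,
                                        "D_sd_um2_s": d_est.dispersion}])
                comparison = compare(exp_df, prediction)
                comparison.to_csv(outdir / "comparison.csv", index=False)

        stage = "summary"
        _stage(stage)
        summary = {
            "config_hash": cfg_hash,
            "seed": config.seed,
            "mode": config.mode,
            "n_tracks": int(tracks["particle"].nunique()),
            "n_observations": int(len(tracks)),
            "D_um2_s": d_est.D,
            "D_sd_um2_s": d_est.dispersion,
            "D_lag_s": d_est.lag_s,
            "alpha": fit.alpha,
            "alpha_window_s": list(fit.window),
            "noise_floor_um2": floor,
            "drift_path_length_um": (drift_est.path_length_um
                                     if drift_est else None),
            "drift_net_displacement_um": (drift_est.net_displacement_um
                                          if drift_est else None),
            "drift_speed_um_s": (drift_est.net_speed_um_s
                                 if drift_est else None),
        }
        if config.gamma_mg_m2 is not None:
            state = monolayer.MonolayerState.from_concentration(config.gamma_mg_m2)
            summary["monolayer"] = {"gamma_mg_m2": state.gamma_mg_m2,
                                    "area_A2": state.area_A2,
                                    "phase": state.phase}
        if comparison is not None:
            summary["comparison"] = comparison.to_dict(orient="records")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
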