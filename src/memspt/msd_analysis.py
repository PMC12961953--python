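"""Drift correction, mean-square-displacement statistics and diffusivity.

The statistical core of the pipeline.  For 2D Brownian motion the MSD obeys

    <dr^2(tau)> = 2 d D tau^alpha,   d = 2,  alpha = 1,

so a log-log fit of the time-and-ensemble-averaged MSD gives the scaling
exponent alpha, and the MSD near a chosen lag (1 s by default — above the
static-noise floor, below the statistics-limited regime) gives D.

Global interfacial drift is removed before the MSD is formed: the mean
displacement of all tracked particles at each frame transition is subtracted
from every particle's displacement at that transition, and the corrected
tracks are rebuilt by cumulative summation from each track's starting point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

@dataclass
class DriftEstimate:
    """Ensemble-average drift recovered from the tracks.

    ``per_frame`` holds the mean displacement vector at each frame
    transition (columns ``frame, dx_um, dy_um``; the entry at frame f is the
    transition f-1 -> f).  ``cumulative`` is its running sum — the estimated
    global drift path.  ``path_length_um`` is the arc length of that path
    (sum of per-transition magnitudes); note that with few particles the
    Brownian part of the ensemble mean inflates the arc length, so for
    near-constant drift ``net_displacement_um`` (straight-line length of the
    cumulative path) is the robust measure of how far the field drifted.
    """

    per_frame: pd.DataFrame
    cumulative: pd.DataFrame
    path_length_um: float
    net_displacement_um: float
    duration_s: float
    n_gaps: int

    @property
    def mean_speed_um_s(self) -> float:
        """Mean drift speed: path length over duration."""
        return self.path_length_um / self.duration_s if self.duration_s > 0 else np.nan

    @property
    def net_speed_um_s(self) -> float:
        return (self.net_displacement_um / self.duration_s
                if self.duration_s > 0 else np.nan)


def correct_drift(tracks: pd.DataFrame, frame_rate: float = 83.3,
                  population: str | None = None
                  ) -> tuple[pd.DataFrame, DriftEstimate]:
    """Subtract the ensemble-average displacement at every frame transition.

    The drift at each transition is the mean displacement over all particles
    observed on both sides of it (optionally restricted to one
    ``population`` label).  Each particle's displacements have that mean
    subtracted and the corrected track is rebuilt by cumulative summation
    from its initial position, so by construction the ensemble-mean
    corrected displacement at every (fully co-observed) transition is zero.
    Transitions with no co-observed particle get zero correction and are
    counted as gaps.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks to drift-correct")
    est_tracks = tracks
    if population is not None:
        est_tracks = tracks[tracks["population"] == population]
        if len(est_tracks) == 0:
            raise ValueError(f"no tracks with population {population!r}")

    wide_x = est_tracks.pivot_table(index="frame", columns="particle",
                                    values="x_um", aggfunc="first")
    wide_y = est_tracks.pivot_table(index="frame", columns="particle",
                                    values="y_um", aggfunc="first")
    f0, f1 = int(tracks["frame"].min()), int(tracks["frame"].max())
    frames = np.arange(f0, f1 + 1)
    wide_x = wide_x.reindex(frames)
    wide_y = wide_y.reindex(frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN transitions
        dx = np.nanmean(np.diff(wide_x.to_numpy(), axis=0), axis=1)
        dy = np.nanmean(np.diff(wide_y.to_numpy(), axis=0), axis=1)
    gaps = ~np.isfinite(dx) | ~np.isfinite(dy)
    n_gaps = int(gaps.sum())
    dx = np.where(gaps, 0.0, dx)
    dy = np.where(gaps, 0.0, dy)

    cum = np.zeros((len(frames), 2))
    cum[1:, 0] = np.cumsum(dx)
    cum[1:, 1] = np.cumsum(dy)
    cum_x = pd.Series(cum[:, 0], index=frames)
    cum_y = pd.Series(cum[:, 1], index=frames)

    corrected = tracks.copy()
    drift_x = cum_x.loc[corrected["frame"]].to_numpy()
    drift_y = cum_y.loc[corrected["frame"]].to_numpy()
    first = tracks.groupby("particle")["frame"].transform("min")
    drift_x0 = cum_x.loc[first].to_numpy()
    drift_y0 = cum_y.loc[first].to_numpy()
    corrected["x_um"] = corrected["x_um"] - (drift_x - drift_x0)
    corrected["y_um"] = corrected["y_um"] - (drift_y - drift_y0)

    per_frame = pd.DataFrame({"frame": frames[1:], "dx_um": dx, "dy_um": dy})
    cumulative = pd.DataFrame({"frame": frames,
                               "dx_um": cum[:, 0], "dy_um": cum[:, 1]})
    step_mag = np.hypot(dx, dy)
    estimate = DriftEstimate(
        per_frame=per_frame, cumulative=cumulative,
        path_length_um=float(step_mag.sum()),
        net_displacement_um=float(np.hypot(cum[-1, 0], cum[-1, 1])),
        duration_s=(len(frames) - 1) / frame_rate,
        n_gaps=n_gaps)
    return corrected, estimate


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Time-and-ensemble-averaged MSD.

    ``msd[k]`` pools every squared displacement over lag ``lag_s[k]`` from
    every start time of every track (observation-weighted average);
    ``n_obs[k]`` counts the pooled displacements.  ``per_particle`` holds
    each particle's own time-averaged MSD (rows: particle id), from which
    the ensemble dispersion at a lag is estimated.
    """

    lag_s: np.ndarray
    msd: np.ndarray
    n_obs: np.ndarray
    per_particle: pd.DataFrame
    d: int = 2
    frame_rate: float = 83.3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_s, "msd_um2": self.msd,
                             "n_obs": self.n_obs})


def compute_msd(tracks: pd.DataFrame, frame_rate: float = 83.3,
                max_lag_s: float | None = None) -> MSDCurve:
    """Compute the time-and-ensemble-averaged MSD of a track table.

    All integer frame lags up to ``max_lag_s`` (default: a quarter of the
    longest track, the usual guard against the statistics-poor tail) are
    evaluated.  Tracks must have unique frames per particle; gaps are
    tolerated (lags are true frame differences).
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    dt = 1.0 / frame_rate
    lengths = tracks.groupby("particle")["frame"].agg(["min", "max"])
    max_span = int((lengths["max"] - lengths["min"]).max())
    if max_span < 1:
        raise ValueError("need at least one track with >= 2 observations")
    if max_lag_s is None:
        max_lag_frames = max(1, max_span // 4)
    else:
        max_lag_frames = int(round(max_lag_s * frame_rate))
        if max_lag_frames > max_span:
            warnings.warn("max_lag exceeds the longest track; truncating",
                          stacklevel=2)
            max_lag_frames = max_span
        max_lag_frames = max(1, max_lag_frames)

    lags = np.arange(1, max_lag_frames + 1)
    sum_sq = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    particle_ids = []
    per_particle_rows = []
    for pid, g in tracks.groupby("particle"):
        g = g.sort_values("frame")
        f = g["frame"].to_numpy(dtype=int)
        xy = g[["x_um", "y_um"]].to_numpy()
        contiguous = len(f) == f[-1] - f[0] + 1
        row = np.full(len(lags), np.nan)
        for k_idx, k in enumerate(lags):
            if contiguous:
                if k >= len(f):
                    break
                disp = xy[k:] - xy[:-k]
            else:
                # gapped track: match observations exactly k frames apart
                pos = {fi: i for i, fi in enumerate(f)}
                pairs = [(i, pos[fi + k]) for i, fi in enumerate(f) if fi + k in pos]
                if not pairs:
                    continue
                a = np.array([p[0] for p in pairs])
                b = np.array([p[1] for p in pairs])
                disp = xy[b] - xy[a]
            sq = (disp ** 2).sum(axis=1)
            sum_sq[k_idx] += sq.sum()
            counts[k_idx] += len(sq)
            row[k_idx] = sq.mean()
        particle_ids.append(pid)
        per_particle_rows.append(row)

    valid = counts > 0
    msd = np.full(len(lags), np.nan)
    msd[valid] = sum_sq[valid] / counts[valid]
    per_particle = pd.DataFrame(per_particle_rows, index=particle_ids,
                                columns=lags * dt)
    return MSDCurve(lag_s=(lags * dt)[valid], msd=msd[valid],
                    n_obs=counts[valid],
                    per_particle=per_particle.loc[:, (lags * dt)[valid]],
                    d=2, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# fits and summaries
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    """Power-law fit MSD = prefactor * tau^alpha over a lag window."""
    alpha: float
    prefactor: float
    window: tuple[float, float]
    residual: float          # RMS residual of log10(msd)
    n_lags: int


def fit_alpha(curve: MSDCurve, window: tuple[float, float] = (0.5, 5.0),
              weighted: bool = True) -> ScalingFit:
    """Least-squares slope of log(MSD) vs log(lag) over ``window`` seconds.

    By default the fit is inverse-variance weighted: the sampling variance
    of a time-averaged MSD grows roughly linearly with lag (displacement
    pairs overlap more at longer lags), so log(MSD) values are weighted by
    1/lag rather than equally.  ``weighted=False`` gives the plain
    ordinary-least-squares slope.  Non-positive MSD values are excluded; at
    least 3 usable lags are required.
    """
    lo, hi = window
    sel = (curve.lag_s >= lo) & (curve.lag_s <= hi) & (curve.msd > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 positive MSD lags in window [{lo}, {hi}] s, "
            f"have {int(sel.sum())}")
    x = np.log(curve.lag_s[sel])
    y = np.log(curve.msd[sel])
    w = 1.0 / curve.lag_s[sel] if weighted else np.ones_like(x)
    w = w / w.sum()
    xbar = (w * x).sum()
    ybar = (w * y).sum()
    slope = ((w * (x - xbar) * (y - ybar)).sum()
             / (w * (x - xbar) ** 2).sum())
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    return ScalingFit(alpha=float(slope),
                      prefactor=float(np.exp(intercept)),
                      window=(lo, hi),
                      residual=float(np.sqrt((w * resid ** 2).sum()) / np.log(10)),
                      n_lags=int(sel.sum()))


@dataclass
class DiffusivityEstimate:
    """Diffusivity from the MSD at (nearest to) a target lag: D = MSD/(2 d tau).

    ``dispersion`` propagates one standard deviation of the per-particle MSD
    at that lag through the same division.
    """
    D: float                 # um^2/s
    lag_s: float
    dispersion: float        # um^2/s
    n_particles: int


def diffusivity_at_lag(curve: MSDCurve, target_lag: float = 1.0,
                       d: int | None = None) -> DiffusivityEstimate:
    """Point estimate of D from the available lag nearest ``target_lag``
    (ties broken toward the smaller lag)."""
    if len(curve.lag_s) == 0:
        raise ValueError("empty MSD curve")
    if d is None:
        d = curve.d
    diff = np.abs(curve.lag_s - target_lag)
    idx = int(np.argmin(diff))  # lags ascending -> first minimum is the smaller lag
    lag = float(curve.lag_s[idx])
    denom = 2.0 * d * lag
    per_part = curve.per_particle.iloc[:, idx].dropna()
    dispersion = float(per_part.std(ddof=1) / denom) if len(per_part) > 1 else np.nan
    return DiffusivityEstimate(D=float(curve.msd[idx] / denom), lag_s=lag,
                               dispersion=dispersion,
                               n_particles=int(per_part.size))


def noise_floor(curve: MSDCurve, rel_slope_tol: float = 0.2) -> float:
    """Lag-averaged MSD of an immobile (static-noise-only) ensemble.

    Static localization noise of per-axis std sigma produces a
    lag-independent 2D MSD of 4 sigma^2; the lag average estimates it.  A
    warning is issued if the MSD varies materially with lag (the input is
    then not static)."""
    floor = float(np.mean(curve.msd))
    if len(curve.lag_s) >= 3 and floor > 0:
        res = stats.linregress(curve.lag_s, curve.msd)
        span = curve.lag_s[-1] - curve.lag_s[0]
        if abs(res.slope) * span > rel_slope_tol * floor:
            warnings.warn(
                "MSD varies with lag; input does not look like static noise",
                stacklevel=2)
    return floor
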