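"""Synthetic ground truth for interfacial single-particle tracking.

Generates 2D Brownian tracks with a shared global drift and Gaussian static
localization noise, and renders them as IRM-like image stacks (dark spots on
a grey background).  Every downstream stage of the pipeline — detection,
linking, drift correction, MSD analysis — can therefore be exercised against
known ground truth without any experimental data.

Coordinate convention (used package-wide): positions are in micrometres in a
frame whose origin is the centre of the top-left pixel, x increasing to the
right (columns), y increasing downward (rows).  Frame indices are 0-based.

Track tables are tidy :class:`pandas.DataFrame` objects with columns
``frame, particle, x_um, y_um`` (plus a ``population`` label), one row per
observation — the same layout the tracking stage produces, so simulated and
re-detected tracks are interchangeable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

TRACK_COLUMNS = ["frame", "particle", "x_um", "y_um"]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Observation model: acquisition timing, optics and noise.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in frames per second.  Default 83.3 fps.
    n_frames : int
        Number of frames in the acquisition (>= 2).
    pixel_size : float
        Physical size of one pixel, micrometres.
    image_shape : tuple of int
        (rows, cols) of the rendered field of view.
    localization_sigma : float
        Per-axis standard deviation of the static localization noise, in
        micrometres.  An immobile particle observed with this noise shows an
        apparent lag-independent MSD floor of ``4 * sigma**2`` in 2D; the
        default 0.05 um reproduces a floor of 0.01 um^2.
    background_level, spot_contrast : float
        Rendering intensities (arbitrary camera units): uniform background
        and how much darker a particle is than the background.
    psf_sigma : float
        Gaussian point-spread-function width, micrometres.
    camera_noise_sigma : float
        Additive per-pixel Gaussian camera noise, intensity units.
    """

    frame_rate: float = 83.3
    n_frames: int = 10_001
    pixel_size: float = 0.2
    image_shape: tuple[int, int] = (512, 512)
    localization_sigma: float = 0.05
    background_level: float = 3000.0
    spot_contrast: float = 1200.0
    psf_sigma: float = 0.3
    camera_noise_sigma: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return (self.n_frames - 1) * self.dt

    @property
    def field_um(self) -> tuple[float, float]:
        """Field of view (height, width) in micrometres."""
        return (self.image_shape[0] * self.pixel_size,
                self.image_shape[1] * self.pixel_size)


@dataclass(frozen=True)
class ParticlePopulation:
    """A homogeneous set of particles sharing geometry and mobility.

    ``radius`` is the physical particle radius used by the hydrodynamic
    model; ``rendered_radius`` is the radius the renderer draws (defaults to
    ``radius``).
    """

    label: str
    n_particles: int
    radius: float            # um
    diffusivity: float       # um^2/s
    rendered_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.diffusivity < 0:
            raise ValueError(f"diffusivity must be >= 0, got {self.diffusivity}")
        if self.rendered_radius is None:
            object.__setattr__(self, "rendered_radius", self.radius)


def default_populations() -> list[ParticlePopulation]:
    """The default mixed ensemble: five 10-um graphene-like disks and twenty
    1-um polystyrene-like spheres, with the diffusivities measured for the
    two classes at a 2.5 mg/m^2 DPPC monolayer (0.035 and 0.15 um^2/s)."""
    return [
        ParticlePopulation("disk10um", 5, radius=5.0, diffusivity=0.035),
        ParticlePopulation("sphere1um", 20, radius=0.5, diffusivity=0.15),
    ]


@dataclass(frozen=True)
class DriftModel:
    """Global interfacial drift shared by every particle.

    ``mode`` is ``"constant"`` (a single velocity vector) or ``"piecewise"``
    (one velocity per segment; ``segment_bounds`` are the segment edges in
    seconds and must cover the full acquisition).
    """

    mode: str = "constant"
    velocity: tuple = (0.0, 0.0)            # um/s, or tuple of vectors
    segment_bounds: tuple = ()               # s, piecewise mode only

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "piecewise"):
            raise ValueError(f"unknown drift mode {self.mode!r}")
        v = np.asarray(self.velocity, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("drift velocities must be finite")
        if self.mode == "piecewise":
            if v.ndim != 2 or v.shape[1] != 2:
                raise ValueError("piecewise mode needs an (n_segments, 2) velocity array")
            b = np.asarray(self.segment_bounds, dtype=float)
            if b.shape != (v.shape[0] + 1,) or np.any(np.diff(b) <= 0):
                raise ValueError("segment_bounds must be increasing with n_segments+1 edges")

    @classmethod
    def none(cls) -> "DriftModel":
        return cls("constant", (0.0, 0.0))

    @classmethod
    def paper_like(cls) -> "DriftModel":
        """Constant drift of 0.75 um/s (~90 um over a 120 s acquisition)."""
        return cls("constant", (0.75, 0.0))

    def velocity_at(self, t: np.ndarray) -> np.ndarray:
        """Drift velocity (um/s) at times ``t`` (s); shape (len(t), 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.mode == "constant":
            return np.broadcast_to(np.asarray(self.velocity, float), (t.size, 2)).copy()
        v = np.asarray(self.velocity, dtype=float)
        b = np.asarray(self.segment_bounds, dtype=float)
        if np.any(t < b[0] - 1e-12) or np.any(t > b[-1] + 1e-12):
            raise ValueError("drift segments do not cover the requested times")
        idx = np.clip(np.searchsorted(b, t, side="right") - 1, 0, v.shape[0] - 1)
        return v[idx]


@dataclass
class GroundTruth:
    """A simulation result: true and observed tracks plus the drift path.

    ``noisy_tracks`` = ``true_tracks`` + localization noise; the true tracks
    already contain the drift, whose cumulative path is recorded separately
    in ``drift_path`` (columns ``frame, dx_um, dy_um``).
    """

    true_tracks: pd.DataFrame
    noisy_tracks: pd.DataFrame
    drift_path: pd.DataFrame
    seed: int
    imaging: ImagingConfig
    populations: list[ParticlePopulation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _initial_positions(n: int, imaging: ImagingConfig, rng: np.random.Generator,
                       margin_frac: float = 0.2,
                       existing: np.ndarray | None = None,
                       min_separation: float = 0.0) -> np.ndarray:
    """Uniform random starting positions inside the central part of the field.

    With ``min_separation`` > 0, positions are rejection-sampled to keep that
    distance (um) from each other and from ``existing`` positions, so
    rendered particles do not start overlapped."""
    h, w = imaging.field_um
    lo = np.array([w * margin_frac, h * margin_frac])
    hi = np.array([w * (1 - margin_frac), h * (1 - margin_frac)])
    if min_separation <= 0:
        return rng.uniform(lo, hi, size=(n, 2))
    placed = [] if existing is None else [np.asarray(p) for p in existing]
    out = []
    for _ in range(n):
        for _attempt in range(1000):
            p = rng.uniform(lo, hi)
            if all(np.hypot(*(p - q)) >= min_separation for q in placed):
                break
        else:
            raise ValueError(
                f"could not place {n} particles at min separation "
                f"{min_separation} um in a {w:.0f}x{h:.0f} um field")
        placed.append(p)
        out.append(p)
    return np.asarray(out)


def simulate_tracks(populations: list[ParticlePopulation],
                    imaging: ImagingConfig,
                    drift: DriftModel | None = None,
                    seed: int = 0) -> GroundTruth:
    """Simulate 2D Brownian tracks with shared drift and localization noise.

    Per-axis increments over one frame interval dt are Gaussian with mean
    ``v_drift * dt`` and variance ``2 * D * dt``, independent across
    particles, axes and frames.  I.i.d. Gaussian localization noise of
    ``imaging.localization_sigma`` per axis is added to each observation.
    Identical seeds give bit-identical output.
    """
    if drift is None:
        drift = DriftModel.none()
    if not populations:
        raise ValueError("at least one particle population is required")
    rng = np.random.default_rng(seed)

    dt = imaging.dt
    nf = imaging.n_frames
    # drift displacement per frame transition, shared by all particles
    t_mid = (np.arange(nf - 1) + 0.5) * dt
    drift_steps = drift.velocity_at(t_mid) * dt            # (nf-1, 2)
    drift_cum = np.vstack([np.zeros(2), np.cumsum(drift_steps, axis=0)])

    frames = np.arange(nf)
    true_parts, noisy_parts = [], []
    pid = 0
    # keep rendered particles from starting overlapped (two rendered radii
    # plus 1 um clearance between any pair)
    max_r = max(p.rendered_radius for p in populations)
    placed: list[np.ndarray] = []
    for pop in populations:
        sep = pop.rendered_radius + max_r + 1.0
        x0 = _initial_positions(pop.n_particles, imaging, rng,
                                existing=np.asarray(placed) if placed else None,
                                min_separation=sep)
        placed.extend(x0)
        sigma_step = np.sqrt(2.0 * pop.diffusivity * dt)
        steps = rng.normal(0.0, sigma_step, size=(pop.n_particles, nf - 1, 2))
        pos = np.empty((pop.n_particles, nf, 2))
        pos[:, 0] = x0
        pos[:, 1:] = x0[:, None, :] + np.cumsum(steps, axis=1)
        pos += drift_cum[None, :, :]
        noise = rng.normal(0.0, imaging.localization_sigma,
                           size=pos.shape) if imaging.localization_sigma > 0 else 0.0
        obs = pos + noise
        for i in range(pop.n_particles):
            true_parts.append(pd.DataFrame({
                "frame": frames, "particle": pid,
                "x_um": pos[i, :, 0], "y_um": pos[i, :, 1],
                "population": pop.label}))
            noisy_parts.append(pd.DataFrame({
                "frame": frames, "particle": pid,
                "x_um": obs[i, :, 0] if imaging.localization_sigma > 0 else pos[i, :, 0],
                "y_um": obs[i, :, 1] if imaging.localization_sigma > 0 else pos[i, :, 1],
                "population": pop.label}))
            pid += 1

    drift_df = pd.DataFrame({"frame": frames,
                             "dx_um": drift_cum[:, 0], "dy_um": drift_cum[:, 1]})
    return GroundTruth(
        true_tracks=pd.concat(true_parts, ignore_index=True),
        noisy_tracks=pd.concat(noisy_parts, ignore_index=True),
        drift_path=drift_df, seed=seed, imaging=imaging,
        populations=list(populations))


def simulate_immobile(n: int, imaging: ImagingConfig, seed: int = 0) -> GroundTruth:
    """Simulate ``n`` immobilized particles: constant true positions, observed
    through localization noise only.  Used to measure the static-noise floor."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = _initial_positions(n, imaging, rng)
    nf = imaging.n_frames
    frames = np.arange(nf)
    pos = np.broadcast_to(x0[:, None, :], (n, nf, 2)).copy()
    obs = pos + (rng.normal(0.0, imaging.localization_sigma, size=pos.shape)
                 if imaging.localization_sigma > 0 else 0.0)
    true_parts, noisy_parts = [], []
    for i in range(n):
        true_parts.append(pd.DataFrame({
            "frame": frames, "particle": i,
            "x_um": pos[i, :, 0], "y_um": pos[i, :, 1], "population": "immobile"}))
        noisy_parts.append(pd.DataFrame({
            "frame": frames, "particle": i,
            "x_um": obs[i, :, 0], "y_um": obs[i, :, 1], "population": "immobile"}))
    drift_df = pd.DataFrame({"frame": frames,
                             "dx_um": np.zeros(nf), "dy_um": np.zeros(nf)})
    return GroundTruth(pd.concat(true_parts, ignore_index=True),
                       pd.concat(noisy_parts, ignore_index=True),
                       drift_df, seed, imaging, [])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_disk(image: np.ndarray, cx_px: float, cy_px: float,
               radius_px: float, contrast: float) -> None:
    # linear edge antialiasing keeps the rendered centroid sub-pixel accurate
    r_int = int(np.ceil(radius_px + 1.5))
    j0 = max(int(np.floor(cy_px)) - r_int, 0)
    j1 = min(int(np.floor(cy_px)) + r_int + 2, image.shape[0])
    i0 = max(int(np.floor(cx_px)) - r_int, 0)
    i1 = min(int(np.floor(cx_px)) + r_int + 2, image.shape[1])
    if j0 >= j1 or i0 >= i1:
        return
    jj, ii = np.mgrid[j0:j1, i0:i1]
    dist = np.hypot(ii - cx_px, jj - cy_px)
    coverage = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    image[j0:j1, i0:i1] -= contrast * coverage


def render_frames(truth: GroundTruth, imaging: ImagingConfig | None = None,
                  seed: int | None = None) -> np.ndarray:
    """Render an observed track set as an IRM-like 16-bit image stack.

    Each particle is drawn as a uniform dark disk of its population's
    ``rendered_radius``, blurred by a Gaussian PSF, on a grey background with
    additive Gaussian camera noise.  Returns ``(n_frames, rows, cols)``
    uint16.  Camera noise is seeded from ``seed`` (default: the truth's own
    seed) so rendering is reproducible.
    """
    if imaging is None:
        imaging = truth.imaging
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    h, w = imaging.image_shape
    px = imaging.pixel_size

    rendered_radius = {}
    for pop in truth.populations:
        rendered_radius[pop.label] = pop.rendered_radius
        if 2 * pop.rendered_radius / px >= min(h, w):
            raise ValueError(
                f"population {pop.label!r} is wider than the image "
                f"({2 * pop.rendered_radius:.1f} um vs {min(h, w) * px:.1f} um field)")

    tracks = truth.noisy_tracks
    nf = imaging.n_frames
    psf_px = imaging.psf_sigma / px
    stack = np.empty((nf, h, w), dtype=np.uint16)
    by_frame = {f: g for f, g in tracks.groupby("frame")}
    default_r = 0.5 * px  # one-pixel point if a track has no population entry
    for f in range(nf):
        frame = np.full((h, w), imaging.background_level, dtype=float)
        g = by_frame.get(f)
        if g is not None:
            for x, y, lab in zip(g["x_um"], g["y_um"], g["population"]):
                r_um = rendered_radius.get(lab, default_r)
                _draw_disk(frame, x / px, y / px, r_um / px, imaging.spot_contrast)
        if psf_px > 0:
            frame = ndimage.gaussian_filter(frame, psf_px, mode="nearest")
        if imaging.camera_noise_sigma > 0:
            frame += rng.normal(0.0, imaging.camera_noise_sigma, size=frame.shape)
        stack[f] = np.clip(frame, 0, 65535).astype(np.uint16)
    return stack


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(stack: np.ndarray, path) -> None:
    """Write an image stack as a lossless multi-page 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_tracks(tracks: pd.DataFrame, path) -> None:
    """Write a track table as CSV with the canonical column order."""
    cols = [c for c in TRACK_COLUMNS if c in tracks.columns]
    cols += [c for c in tracks.columns if c not in cols]
    tracks[cols].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    tracks = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return tracks


def write_drift_path(drift_path: pd.DataFrame, path) -> None:
    drift_path.to_csv(path, index=False)
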