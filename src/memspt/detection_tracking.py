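"""Particle detection and track linking (Crocker–Grier scheme).

The classic colloid-tracking recipe: spatial bandpass (short-scale Gaussian
smoothing minus a boxcar background over the feature size), local-maximum
candidate selection, intensity-weighted centroid refinement to sub-pixel
precision, and frame-to-frame nearest-neighbour linking with greedy
minimal-displacement assignment.

Dark-on-grey (IRM-like) images are handled by inverting before the bandpass
so that features are always intensity maxima.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "intensity", "radius_um_est"]


# ---------------------------------------------------------------------------
# image filtering
# ---------------------------------------------------------------------------

def bandpass(image: np.ndarray, noise_length: float = 1.0,
             feature_diameter: int = 9, invert: bool = False) -> np.ndarray:
    """Bandpass-filter one frame: suppress pixel noise below ``noise_length``
    and background variation above ``feature_diameter``.

    Returns the short-scale smoothed image minus the boxcar background over
    the feature size, clipped at zero.  ``invert=True`` flips contrast first
    so dark spots become maxima.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("bandpass expects a single 2D frame")
    if noise_length < 1:
        raise ValueError("noise_length must be >= 1 pixel")
    if feature_diameter <= noise_length:
        raise ValueError("feature_diameter must exceed noise_length")
    if feature_diameter >= min(image.shape):
        raise ValueError(
            f"feature_diameter {feature_diameter} >= image size {min(image.shape)}")
    if invert:
        image = -image
    boxcar_size = 2 * (int(feature_diameter) // 2) + 1
    smoothed = ndimage.gaussian_filter(image, noise_length, mode="nearest")
    background = ndimage.uniform_filter(image, boxcar_size, mode="nearest")
    return np.clip(smoothed - background, 0.0, None)


# ---------------------------------------------------------------------------
# centroid location
# ---------------------------------------------------------------------------

def locate(filtered: np.ndarray, feature_diameter: int = 9,
           intensity_threshold: float = 99.0, pixel_size: float = 1.0,
           min_mass: float = 0.0, max_refine_iter: int = 5) -> pd.DataFrame:
    """Find sub-pixel particle centroids in a bandpassed frame.

    Candidates are local maxima within a ``feature_diameter`` neighbourhood
    whose value exceeds the ``intensity_threshold`` percentile of the
    filtered image.  Each candidate is refined to the intensity-weighted
    centroid inside a circular mask of radius ``feature_diameter / 2``,
    re-centred while the estimate moves by more than half a pixel.
    Candidates whose integrated mass falls below ``min_mass`` are discarded
    (suppresses weak spurious maxima).

    Returns a DataFrame with ``x_um, y_um`` (physical units), ``intensity``
    (integrated mass) and ``radius_um_est`` (uniform-disk-equivalent radius
    from the radius of gyration).  The ``frame`` column is left to the
    caller.  A blank frame yields an empty table.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.min() < 0:
        raise ValueError("locate expects a nonnegative (bandpassed) image")
    w = feature_diameter / 2.0
    size = 2 * (int(feature_diameter) // 2) + 1
    empty = pd.DataFrame({c: pd.Series(dtype=float) for c in DETECTION_COLUMNS[1:]})
    if not np.any(filtered > 0):
        return empty

    threshold = np.percentile(filtered, intensity_threshold)
    maxima = (filtered == ndimage.maximum_filter(filtered, size=size, mode="nearest"))
    cand = np.argwhere(maxima & (filtered > threshold) & (filtered > 0))
    if cand.size == 0:
        return empty

    r_int = int(np.ceil(w))
    off = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    mask = (off[0] ** 2 + off[1] ** 2) <= w ** 2
    dj, di = off[0][mask], off[1][mask]
    h, wid = filtered.shape

    rows = []
    for j, i in cand:
        # drop candidates whose mask would fall off the image edge
        if j < r_int or i < r_int or j >= h - r_int or i >= wid - r_int:
            continue
        cj, ci = float(j), float(i)
        for _ in range(max_refine_iter):
            jj = np.round(cj).astype(int) + dj
            ii = np.round(ci).astype(int) + di
            inside = (jj >= 0) & (jj < h) & (ii >= 0) & (ii < wid)
            vals = filtered[jj[inside], ii[inside]]
            mass = vals.sum()
            if mass <= 0:
                break
            new_cj = float((vals * jj[inside]).sum() / mass)
            new_ci = float((vals * ii[inside]).sum() / mass)
            shift = np.hypot(new_cj - cj, new_ci - ci)
            cj, ci = new_cj, new_ci
            if shift <= 0.5:
                break
        if mass <= 0 or mass < min_mass:
            continue
        r2 = ((jj[inside] - cj) ** 2 + (ii[inside] - ci) ** 2)
        rg2 = float((vals * r2).sum() / mass)
        # uniform disk of radius R has radius of gyration R / sqrt(2)
        rows.append((ci * pixel_size, cj * pixel_size, mass,
                     np.sqrt(2.0 * rg2) * pixel_size))
    if not rows:
        return empty
    out = pd.DataFrame(rows, columns=["x_um", "y_um", "intensity", "radius_um_est"])
    # merge duplicate candidates that refined to the same centroid
    out = out.sort_values(["x_um", "y_um"], kind="stable").reset_index(drop=True)
    keep = np.ones(len(out), dtype=bool)
    xy = out[["x_um", "y_um"]].to_numpy()
    for a in range(len(out)):
        if not keep[a]:
            continue
        d = np.hypot(xy[a + 1:, 0] - xy[a, 0], xy[a + 1:, 1] - xy[a, 1])
        keep[a + 1:] &= d > 0.5 * w * pixel_size
    return out[keep].reset_index(drop=True)


def detect_stack(stack: np.ndarray, feature_diameter: int = 9,
                 intensity_threshold: float = 99.0, pixel_size: float = 1.0,
                 noise_length: float = 1.0, invert: bool = True) -> pd.DataFrame:
    """Bandpass + locate every frame of a stack; returns the detection table
    with ``frame`` filled in."""
    frames = []
    for f, image in enumerate(stack):
        det = locate(bandpass(image, noise_length, feature_diameter, invert=invert),
                     feature_diameter, intensity_threshold, pixel_size)
        if len(det):
            det.insert(0, "frame", f)
            frames.append(det)
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in DETECTION_COLUMNS})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link(detections: pd.DataFrame, max_displacement: float,
         memory: int = 0) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    Candidate (track, detection) pairs within ``max_displacement`` (um) are
    ranked by displacement and assigned greedily from the smallest, each side
    used at most once.  Unmatched detections start new tracks; a track
    unmatched for more than ``memory`` frames is closed.  Every detection
    ends up in exactly one track.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    if len(detections) == 0:
        out = detections.copy()
        out["particle"] = pd.Series(dtype=int)
        return out

    detections = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    particle_of = np.full(len(detections), -1, dtype=int)
    # active tracks: id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    next_id = 0
    for frame, group in detections.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that have been unmatched too long
        active = {tid: s for tid, s in active.items()
                  if frame - s[0] <= memory + 1}
        idx = group.index.to_numpy()
        xy = group[["x_um", "y_um"]].to_numpy()
        pairs = []
        for tid, (lf, lx, ly) in active.items():
            d = np.hypot(xy[:, 0] - lx, xy[:, 1] - ly)
            for k in np.nonzero(d <= max_displacement)[0]:
                pairs.append((d[k], tid, k))
        pairs.sort(key=lambda p: p[0])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, tid, k in pairs:
            if tid in used_tracks or k in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(k)
            particle_of[idx[k]] = tid
            active[tid] = (frame, xy[k, 0], xy[k, 1])
        for k in range(len(idx)):
            if k not in used_dets:
                particle_of[idx[k]] = next_id
                active[next_id] = (frame, xy[k, 0], xy[k, 1])
                next_id += 1

    out = detections.copy()
    out["particle"] = particle_of
    cols = ["frame", "particle"] + [c for c in out.columns
                                    if c not in ("frame", "particle")]
    return out[cols].sort_values(["particle", "frame"],
                                 kind="stable").reset_index(drop=True)


def filter_tracks(tracks: pd.DataFrame, min_length: int = 2) -> pd.DataFrame:
    """Drop tracks with fewer than ``min_length`` observations and re-index
    the surviving particle ids stably (order of first appearance)."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    counts = tracks.groupby("particle")["frame"].size()
    keep = counts[counts >= min_length].index
    out = tracks[tracks["particle"].isin(keep)].copy()
    if len(out) == 0:
        return out.reset_index(drop=True)
    order = (out.groupby("particle")["frame"].min()
                .sort_values(kind="stable").index)
    remap = {old: new for new, old in enumerate(order)}
    out["particle"] = out["particle"].map(remap)
    return out.sort_values(["particle", "frame"], kind="stable").reset_index(drop=True)


def split_by_size(tracks: pd.DataFrame, cut_um: float = 3.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate tracks into (large, small) classes by each track's median
    estimated spot radius; the default 3 um cut separates 10-um disks from
    1-um spheres."""
    med = tracks.groupby("particle")["radius_um_est"].median()
    large_ids = med[med >= cut_um].index
    is_large = tracks["particle"].isin(large_ids)
    return (tracks[is_large].reset_index(drop=True),
            tracks[~is_large].reset_index(drop=True))


def track_stack(stack: np.ndarray, pixel_size: float, feature_diameter: int = 9,
                intensity_threshold: float = 99.0, max_displacement: float = 1.0,
                min_length: int = 2, memory: int = 0, noise_length: float = 1.0,
                invert: bool = True) -> pd.DataFrame:
    """Full image-to-tracks pipeline: detect every frame, link, filter."""
    detections = detect_stack(stack, feature_diameter, intensity_threshold,
                              pixel_size, noise_length, invert)
    return filter_tracks(link(detections, max_displacement, memory), min_length)
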