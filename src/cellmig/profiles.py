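"""Fluorescence line-scan extraction, registration, averaging and enrichment.

A line scan samples a multi-channel image along a user-drawn segment
(1-px steps, bilinear interpolation, averaged across a perpendicular
width).  Scans are registered to a landmark — the maximum of a reference
channel (cell edge mode) or a user-annotated zero (junction mode) —
resampled to a common signed-distance grid, normalised per profile to
percent-of-max, and averaged to mean ± SEM.  ``edge_enrichment`` computes
the fold ratio of mean intensity between an edge band and a matched band
beneath the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.measure import profile_line

__all__ = [
    "LineProfile",
    "extract_profile",
    "register_profiles",
    "average_profiles",
    "edge_enrichment",
]


@dataclass(frozen=True)
class LineProfile:
    """Intensity along a line, all channels on a shared distance grid.

    ``distance_um`` is signed position relative to the landmark (0 at the
    cell edge or junction once registered); ``intensity`` has shape
    (n_channels, n_samples).
    """

    distance_um: np.ndarray
    intensity: np.ndarray
    source: str = ""

    def __post_init__(self):
        d = np.asarray(self.distance_um, dtype=float)
        inten = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if inten.shape[1] != d.size:
            raise ValueError("intensity and distance grids disagree")
        steps = np.diff(d)
        if d.size > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("distance grid must be uniform")
        object.__setattr__(self, "distance_um", d)
        object.__setattr__(self, "intensity", inten)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def step_um(self) -> float:
        return float(self.distance_um[1] - self.distance_um[0])


def extract_profile(
    image: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
    pixel_um: float = 1.0,
    source: str = "",
) -> LineProfile:
    """Sample a multi-channel image along a line at 1-px steps.

    ``image`` is (H, W) or (n_channels, H, W); ``line`` is ((x0, y0),
    (x1, y1)) in pixel coordinates.  Each sample is the mean over
    ``width_px`` bilinear samples perpendicular to the line.  Lines (or
    their width extent) leaving the image raise ``ValueError``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    (x0, y0), (x1, y1) = line
    _, H, W = img.shape
    length = np.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("degenerate line of zero length")
    # half-width extent perpendicular to the line must stay inside the image
    nx, ny = -(y1 - y0) / length, (x1 - x0) / length
    hw = (width_px - 1) / 2.0
    for (px, py) in ((x0, y0), (x1, y1)):
        for s in (-hw, hw):
            qx, qy = px + s * nx, py + s * ny
            if not (0 <= qx <= W - 1 and 0 <= qy <= H - 1):
                raise ValueError("line (with width) exits the image")

    channels = [
        profile_line(ch, (y0, x0), (y1, x1), linewidth=width_px,
                     order=1, mode="constant", reduce_func=np.mean)
        for ch in img
    ]
    inten = np.vstack(channels)
    dist = np.arange(inten.shape[1]) * pixel_um
    return LineProfile(distance_um=dist, intensity=inten, source=source)


@dataclass(frozen=True)
class RegistrationResult:
    profiles: list[LineProfile]
    rejected: list[tuple[str, str]]  # (source, reason)


def register_profiles(
    profs: Sequence[LineProfile],
    reference_channel: int = 0,
    mode: Literal["edge", "junction"] = "edge",
    window_um: tuple[float, float] = (-2.5, 2.5),
    landmarks_um: Sequence[float] | None = None,
) -> RegistrationResult:
    """Register line scans to a common landmark and resample to one grid.

    In ``edge`` mode the landmark is the position of the reference-channel
    maximum; profiles whose maximum sits at a scan end (peak clipped) or
    whose reference channel is flat are rejected with a reason.  In
    ``junction`` mode the caller supplies the landmark position per profile
    (``landmarks_um``).  All kept profiles are linearly resampled onto a
    common grid spanning ``window_um`` around the landmark.
    """
    if not profs:
        raise ValueError("no profiles to register")
    if mode == "junction":
        if landmarks_um is None or len(landmarks_um) != len(profs):
            raise ValueError("junction mode needs one landmark per profile")
    step = min(p.step_um for p in profs)
    lo, hi = window_um
    grid = np.arange(lo, hi + step / 2, step)

    kept: list[LineProfile] = []
    rejected: list[tuple[str, str]] = []
    for i, p in enumerate(profs):
        ref = p.intensity[reference_channel]
        if mode == "edge":
            if np.ptp(ref) == 0:
                rejected.append((p.source or str(i), "flat reference channel"))
                continue
            imax = int(np.argmax(ref))
            if imax == 0 or imax == ref.size - 1:
                rejected.append((p.source or str(i), "reference maximum at scan end"))
                continue
            landmark = p.distance_um[imax]
        else:
            landmark = float(landmarks_um[i])
        shifted = p.distance_um - landmark
        resampled = np.vstack([
            np.interp(grid, shifted, ch, left=np.nan, right=np.nan)
            for ch in p.intensity
        ])
        kept.append(LineProfile(distance_um=grid, intensity=resampled, source=p.source))
    return RegistrationResult(profiles=kept, rejected=rejected)


def average_profiles(
    profs: Sequence[LineProfile],
    normalize: Literal["percent_max", "percent_sum", "none"] = "percent_max",
) -> pd.DataFrame:
    """Pointwise mean ± SEM per channel across registered profiles.

    With ``percent_max`` each profile is first scaled per channel so its
    maximum is 100%; ``percent_sum`` scales so the channel sums to 100.
    Returns a long-format table (distance_um, channel, mean, sem, n).
    """
    if len(profs) < 2:
        raise ValueError("averaging needs >= 2 profiles")
    grid = profs[0].distance_um
    n_ch = profs[0].n_channels
    for p in profs[1:]:
        if p.n_channels != n_ch or p.distance_um.shape != grid.shape or not np.allclose(p.distance_um, grid):
            raise ValueError("profiles are not on a common grid")
    rows = []
    for c in range(n_ch):
        mat = np.vstack([p.intensity[c] for p in profs])
        if normalize == "percent_max":
            scale = np.nanmax(mat, axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            mat = 100.0 * mat / scale
        elif normalize == "percent_sum":
            scale = np.nansum(mat, axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            mat = 100.0 * mat / scale
        n = np.sum(~np.isnan(mat), axis=0)
        mean = np.nanmean(mat, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        rows.append(pd.DataFrame({"distance_um": grid, "channel": c, "mean": mean,
                                  "sem": sem, "n": n}))
    return pd.concat(rows, ignore_index=True)


def edge_enrichment(
    image: np.ndarray,
    edge_band: np.ndarray,
    inner_band: np.ndarray,
    background: float = 0.0,
    area_tol: float = 0.10,
) -> float:
    """Fold enrichment at the cell edge relative to a band beneath the membrane.

    ``edge_band`` and ``inner_band`` are boolean ROI masks of (near-)equal
    area (within ``area_tol``) that must not overlap.  The ratio of
    background-subtracted mean intensities is returned.
    """
    img = np.asarray(image, dtype=float)
    eb = np.asarray(edge_band, dtype=bool)
    ib = np.asarray(inner_band, dtype=bool)
    if eb.shape != img.shape or ib.shape != img.shape:
        raise ValueError("ROI masks must match the image shape")
    if (eb & ib).any():
        raise ValueError("edge and inner ROIs overlap")
    a_e, a_i = eb.sum(), ib.sum()
    if a_e == 0 or a_i == 0:
        raise ValueError("empty ROI")
    if abs(a_e - a_i) > area_tol * max(a_e, a_i):
        raise ValueError(f"ROI areas differ by more than {area_tol:.0%}: {a_e} vs {a_i}")
    inner_mean = img[ib].mean() - background
    if inner_mean <= 0:
        raise ValueError("inner ROI mean <= 0 after background subtraction")
    return float((img[eb].mean() - background) / inner_mean)


def read_line_annotations(path) -> pd.DataFrame:
    """Read line annotations: image,line_id,x0,y0,x1,y1,width_px."""
    df = pd.read_csv(path)
    required = ["image", "line_id", "x0", "y0", "x1", "y1", "width_px"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"line annotation CSV missing columns: {missing}")
    return df
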