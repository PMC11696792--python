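"""Particle image velocimetry on consecutive frame pairs.

Single-pass windowed cross-correlation: each interrogation window (default
32 px with 0.75 overlap, i.e. one vector every 8 px) of frame A is
mean-subtracted and correlated against the same window of frame B via FFT;
the correlation peak gives the integer displacement and a 3-point Gaussian
fit in x and y refines it to subpixel precision.  Post-processing follows
the usual PIV pipeline: spurious vectors are filtered on amplitude
(mean ± k·SD of the field) and replaced by interpolation from neighbouring
vectors, then fields are averaged over a sliding time window (default
4 frames = 40 min at a 10-min frame interval).

Coordinates are image coordinates: origin top-left, y increasing downward,
displacements in px/frame; ``to_velocity`` converts to µm/h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PivConfig",
    "VectorField",
    "piv_pair",
    "piv_stack",
    "validate_and_fill",
    "smooth_time",
    "to_velocity",
]


@dataclass(frozen=True)
class PivConfig:
    """PIV settings.

    ``window_px`` is the interrogation window edge (32 px = 23.75 µm at the
    default camera scale), ``overlap`` the fraction shared by adjacent
    windows, ``time_avg_frames`` the sliding-average length and
    ``outlier_k`` the SD multiplier of the amplitude filter.
    """

    window_px: int = 32
    overlap: float = 0.75
    pixel_um: float = 0.7422
    dt_min: float = 10.0
    time_avg_frames: int = 4
    outlier_k: float = 3.0

    def __post_init__(self):
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if self.window_px < 4:
            raise ValueError("window_px too small")
        if self.step_px < 1:
            raise ValueError("grid step must be >= 1 px")

    @property
    def step_px(self) -> int:
        return int(round(self.window_px * (1.0 - self.overlap)))


@dataclass(frozen=True)
class VectorField:
    """Gridded displacement estimates from one frame pair.

    ``u``/``v`` are displacements in px/frame along image x (columns) and
    y (rows, downward); ``peak_quality`` is the ratio of the highest to the
    second-highest correlation peak; ``valid`` marks usable vectors.
    """

    grid_x: np.ndarray   # (ny, nx) window-centre columns, px
    grid_y: np.ndarray   # (ny, nx) window-centre rows, px
    u: np.ndarray
    v: np.ndarray
    peak_quality: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def to_dataframe(self, cfg: PivConfig | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x_px": self.grid_x.ravel(),
                "y_px": self.grid_y.ravel(),
                "u_px": self.u.ravel(),
                "v_px": self.v.ravel(),
                "peak_q": self.peak_quality.ravel(),
                "valid": self.valid.ravel(),
            }
        )
        if cfg is not None:
            scale = cfg.pixel_um * 60.0 / cfg.dt_min
            df["u_umh"] = df["u_px"] * scale
            df["v_umh"] = df["v_px"] * scale
        return df


def _gauss_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """3-point Gaussian peak interpolation; 0 if the log fit degenerates."""
    eps = 1e-12
    lm1, l0, lp1 = (np.log(max(c, eps)) for c in (cm1, c0, cp1))
    denom = 2.0 * (lm1 + lp1 - 2.0 * l0)
    if denom >= -eps:  # not a local max in log space
        return 0.0
    return float((lm1 - lp1) / denom)


def piv_pair(frame_a: np.ndarray, frame_b: np.ndarray, cfg: PivConfig = PivConfig()) -> VectorField:
    """Displacement field from frame A to frame B.

    Windows are mean-subtracted and correlated in the Fourier domain
    (circular correlation); the displacement is the peak location relative
    to zero shift, refined by a 3-point Gaussian fit.  Windows with zero
    intensity variance (e.g. inside the cell-free wound) yield an invalid
    vector.  Windows overhanging the frame are dropped.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be equal-sized 2-D arrays")
    w = cfg.window_px
    if min(a.shape) < w:
        raise ValueError(f"frame smaller than the {w}-px interrogation window")
    step = cfg.step_px
    H, W = a.shape
    ys = np.arange(0, H - w + 1, step)
    xs = np.arange(0, W - w + 1, step)
    ny, nx = ys.size, xs.size

    # stack all windows: (ny*nx, w, w)
    wa = np.lib.stride_tricks.sliding_window_view(a, (w, w))[np.ix_(ys, xs)].reshape(-1, w, w)
    wb = np.lib.stride_tricks.sliding_window_view(b, (w, w))[np.ix_(ys, xs)].reshape(-1, w, w)
    mean_a = wa.mean(axis=(1, 2), keepdims=True)
    mean_b = wb.mean(axis=(1, 2), keepdims=True)
    flat = (np.einsum("kij,kij->k", wa - mean_a, wa - mean_a) <= 0) | (
        np.einsum("kij,kij->k", wb - mean_b, wb - mean_b) <= 0
    )

    # normalised cross-correlation, linear (zero-padded) so that broad
    # image textures do not bias the peak toward zero shift: the Pearson
    # correlation over each overlap region, all sums computed by FFT
    n_pad = 2 * w
    shape = (n_pad, n_pad)
    ones = np.ones((w, w))
    fm = np.fft.rfft2(ones, s=shape)
    fa = np.fft.rfft2(wa, s=shape)
    fb = np.fft.rfft2(wb, s=shape)
    fa2 = np.fft.rfft2(wa * wa, s=shape)
    fb2 = np.fft.rfft2(wb * wb, s=shape)

    def xcorr(f1, f2):
        return np.fft.fftshift(np.fft.irfft2(np.conj(f1) * f2, s=shape), axes=(-2, -1))

    s_ab = xcorr(fa, fb)
    s_a = xcorr(fa, fm[None])
    s_b = xcorr(fm[None], fb)
    s_a2 = xcorr(fa2, fm[None])
    s_b2 = xcorr(fm[None], fb2)

    centre = n_pad // 2
    shifts = np.arange(n_pad) - centre
    n_overlap = np.outer(*(np.maximum(w - np.abs(shifts), 0.0),) * 2)
    n_safe = np.maximum(n_overlap, 1.0)
    var_a = np.maximum(s_a2 - s_a * s_a / n_safe, 0.0)
    var_b = np.maximum(s_b2 - s_b * s_b / n_safe, 0.0)
    eps = 1e-9 * float(np.max(var_a) + np.max(var_b) + 1.0)
    corr = (s_ab - s_a * s_b / n_safe) / np.sqrt(np.maximum(var_a * var_b, eps))

    # restrict the search to |shift| <= w/2 (the validity bound)
    half = w // 2
    search = (np.abs(shifts)[:, None] <= half) & (np.abs(shifts)[None, :] <= half)

    u = np.zeros(ny * nx)
    v = np.zeros(ny * nx)
    quality = np.zeros(ny * nx)
    valid = ~flat
    for k in range(ny * nx):
        if flat[k]:
            continue
        c = np.where(search, corr[k], -np.inf)
        iy, ix = np.unravel_index(np.argmax(c), c.shape)
        dy, dx = iy - centre, ix - centre
        peak = c[iy, ix]
        # subpixel refinement needs neighbours around an interior peak
        if abs(dx) < half:
            dx += _gauss_subpixel(c[iy, ix - 1], peak, c[iy, ix + 1])
        if abs(dy) < half:
            dy += _gauss_subpixel(c[iy - 1, ix], peak, c[iy + 1, ix])
        u[k], v[k] = dx, dy
        # second peak outside a 3x3 exclusion zone around the primary
        cm = c.copy()
        cm[iy - 1: iy + 2, ix - 1: ix + 2] = -np.inf
        second = float(np.max(cm))
        quality[k] = peak / second if second > 0 else np.inf

    gx, gy = np.meshgrid(xs + (w - 1) / 2.0, ys + (w - 1) / 2.0)
    return VectorField(
        grid_x=gx, grid_y=gy,
        u=u.reshape(ny, nx), v=v.reshape(ny, nx),
        peak_quality=quality.reshape(ny, nx), valid=valid.reshape(ny, nx),
    )


def validate_and_fill(fld: VectorField, cfg: PivConfig = PivConfig()) -> VectorField:
    """Amplitude-filter spurious vectors and fill gaps by neighbour interpolation.

    Vectors whose magnitude lies outside mean ± outlier_k·SD of the valid
    field are marked invalid; every invalid vector is then replaced by the
    inverse-distance-weighted mean of its valid 8-neighbourhood, iterating
    until the grid is filled.  Already-valid vectors are never modified.
    """
    mag = fld.magnitude()
    valid = fld.valid.copy()
    if valid.sum() == 0:
        raise ValueError("field unusable: no valid vectors")
    m, s = mag[valid].mean(), mag[valid].std()
    outlier = valid & (np.abs(mag - m) > cfg.outlier_k * s)
    valid = valid & ~outlier
    if valid.sum() < 0.5 * valid.size:
        raise ValueError("field unusable: more than 50% of vectors invalid")

    u = np.where(valid, fld.u, np.nan)
    v = np.where(valid, fld.v, np.nan)
    ny, nx = u.shape
    # inverse-distance weights of the 8-neighbourhood
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    weights = [1.0 / np.hypot(dy, dx) for dy, dx in offsets]
    filled = valid.copy()
    while not filled.all():
        new_u, new_v = u.copy(), v.copy()
        newly = np.zeros_like(filled)
        for i in range(ny):
            for j in range(nx):
                if filled[i, j]:
                    continue
                num_u = num_v = den = 0.0
                for (dy, dx), wgt in zip(offsets, weights):
                    ii, jj = i + dy, j + dx
                    if 0 <= ii < ny and 0 <= jj < nx and filled[ii, jj]:
                        num_u += wgt * u[ii, jj]
                        num_v += wgt * v[ii, jj]
                        den += wgt
                if den > 0:
                    new_u[i, j] = num_u / den
                    new_v[i, j] = num_v / den
                    newly[i, j] = True
        if not newly.any():
            raise ValueError("field unusable: holes cannot be filled")
        u, v = new_u, new_v
        filled |= newly

    return VectorField(
        grid_x=fld.grid_x, grid_y=fld.grid_y, u=u, v=v,
        peak_quality=fld.peak_quality, valid=np.ones_like(valid, dtype=bool),
    )


def smooth_time(fields: Sequence[VectorField], cfg: PivConfig = PivConfig()) -> list[VectorField]:
    """Trailing sliding-window mean over ``time_avg_frames`` consecutive fields.

    Output t is the mean of fields t..t+L-1 (labelled by the window's first
    frame, preserving t0 at the left); the sequence shrinks by L-1.
    """
    L = cfg.time_avg_frames
    if len(fields) < L:
        raise ValueError(f"need at least {L} fields for the sliding average")
    g0x, g0y = fields[0].grid_x, fields[0].grid_y
    for f in fields[1:]:
        if f.grid_x.shape != g0x.shape or not (np.allclose(f.grid_x, g0x) and np.allclose(f.grid_y, g0y)):
            raise ValueError("fields are not on a common grid")
    out = []
    for t in range(len(fields) - L + 1):
        chunk = fields[t: t + L]
        u = np.mean([f.u for f in chunk], axis=0)
        v = np.mean([f.v for f in chunk], axis=0)
        q = np.mean([f.peak_quality for f in chunk], axis=0)
        valid = np.logical_and.reduce([f.valid for f in chunk])
        out.append(VectorField(g0x, g0y, u, v, q, valid))
    return out


def to_velocity(fld: VectorField, cfg: PivConfig = PivConfig()) -> VectorField:
    """Convert displacements (px/frame) to velocities (µm/h) on the same grid."""
    scale = cfg.pixel_um * 60.0 / cfg.dt_min
    return replace(fld, u=fld.u * scale, v=fld.v * scale)


def piv_stack(frames: np.ndarray, cfg: PivConfig = PivConfig(),
              postprocess: bool = True) -> list[VectorField]:
    """PIV on every consecutive frame pair of a stack; optionally
    amplitude-filter/fill and time-average per the configuration."""
    fields = [piv_pair(frames[k], frames[k + 1], cfg) for k in range(len(frames) - 1)]
    if postprocess:
        fields = [validate_and_fill(f, cfg) for f in fields]
        if len(fields) >= cfg.time_avg_frames:
            fields = smooth_time(fields, cfg)
    return fields


def write_fields(fields: Sequence[VectorField], cfg: PivConfig, out_dir) -> None:
    """Write one CSV per frame pair plus a stack-level JSON manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    names = []
    for k, f in enumerate(fields):
        name = f"field_{k:04d}.csv"
        f.to_dataframe(cfg).to_csv(os.path.join(out_dir, name), index=False)
        names.append(name)
    manifest = {
        "n_fields": len(fields),
        "window_px": cfg.window_px,
        "overlap": cfg.overlap,
        "pixel_um": cfg.pixel_um,
        "dt_min": cfg.dt_min,
        "files": names,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
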