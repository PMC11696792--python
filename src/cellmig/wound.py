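"""Collective-migration analysis of wound-healing movies.

The cell-free wound is segmented as the low-texture region of each frame
(local intensity SD below an automatically chosen threshold), the leading
edge is the
monolayer/wound boundary averaged over columns, and PIV vector fields are
summarised as space-time maps: a scalar (speed in µm/h, or the order
parameter = cosine of the angle between each displacement vector and the
wound-ward direction) binned by distance from the front edge (rows, front
edge at the top) and by time since insert lifting (columns).
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk

from .piv import PivConfig, VectorField

__all__ = [
    "WoundGeometry",
    "SpaceTimeMap",
    "segment_wound",
    "edge_progression",
    "order_parameter",
    "build_heatmap",
    "profile_at_time",
]


@dataclass(frozen=True)
class WoundGeometry:
    """Where the wound is relative to the image.

    ``wound_side`` is the image side on which the cell-free region lies
    ('top', 'bottom', 'left' or 'right'); the wound axis runs perpendicular
    to the progression direction.  ``edge_px`` holds, per frame, the
    boundary coordinate per column (or per row for left/right wounds).
    """

    wound_side: Literal["top", "bottom", "left", "right"]
    edge_px: list[np.ndarray]  # per frame, per column (NaN where no boundary)
    pixel_um: float = 0.7422

    @property
    def wound_axis(self) -> int:
        """Image axis along which the wound runs (0 = rows, 1 = columns)."""
        return 1 if self.wound_side in ("top", "bottom") else 0

    def normal_toward_wound(self) -> np.ndarray:
        """Unit vector (dx, dy), image coordinates, pointing into the wound."""
        return {
            "top": np.array([0.0, -1.0]),
            "bottom": np.array([0.0, 1.0]),
            "left": np.array([-1.0, 0.0]),
            "right": np.array([1.0, 0.0]),
        }[self.wound_side]

    def mean_edge(self, frame_idx: int) -> float:
        e = self.edge_px[frame_idx]
        if np.all(np.isnan(e)):
            raise ValueError(f"frame {frame_idx}: no wound boundary")
        return float(np.nanmean(e))


def _local_sd(frame: np.ndarray, radius: int = 8) -> np.ndarray:
    """Local intensity standard deviation with a disk-shaped footprint."""
    yy, xx = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    disk = (yy**2 + xx**2 <= radius**2).astype(float)
    f = frame.astype(float)
    # normalised convolution: divide by the in-image kernel coverage so the
    # image border does not produce a spurious high-variance band
    coverage = fftconvolve(np.ones_like(f), disk, mode="same")
    mean = fftconvolve(f, disk, mode="same") / coverage
    mean_sq = fftconvolve(f * f, disk, mode="same") / coverage
    return np.sqrt(np.maximum(mean_sq - mean * mean, 0.0))


def segment_wound(frame: np.ndarray, wound_side: str = "top",
                  sd_radius: int = 8) -> np.ndarray:
    """Binary mask of the cell-free wound region of one grayscale frame.

    The wound is the largest connected component of low local texture
    (local SD below an automatic threshold, Otsu-initialised) touching
    ``wound_side``.  Raises if no low-texture component exists there.
    """
    sd = _local_sd(frame, sd_radius)
    # isodata-style iteration with a geometric class mean, initialised at
    # Otsu: local-SD scales of wound floor and texture differ by an order
    # of magnitude, so Otsu's split sits inside the textured class's lower
    # tail (and drifts as the wound shrinks); the geometric fixed point
    # settles in the gap between the two scales
    thr = float(threshold_otsu(sd))
    lo_med = hi_med = None
    for _ in range(50):
        lo = sd[sd < thr]
        hi = sd[sd >= thr]
        if lo.size == 0 or hi.size == 0:
            break
        hi_med = float(np.median(hi))
        # a perfectly flat wound has local SD ~0 (down to quantisation and
        # FFT round-off); keep the split a fixed fraction below the
        # textured class rather than chasing it to zero
        lo_med = max(float(np.median(lo)), 1e-4 * hi_med, 1e-12)
        new = float(np.sqrt(lo_med * hi_med))
        if abs(new - thr) <= 1e-3 * thr:
            thr = new
            break
        thr = new
    # a genuine cell-free region is an order of magnitude smoother than the
    # monolayer; if the two classes are not clearly separated the frame has
    # no wound to segment
    if lo_med is None or hi_med < 2.0 * lo_med:
        raise ValueError("wound not found: no low-texture region")
    low = sd < thr
    if not low.any():
        raise ValueError("wound not found: no low-texture region")
    labels = cc_label(low, connectivity=2)
    edge_slice = {
        "top": (slice(0, 1), slice(None)),
        "bottom": (slice(-1, None), slice(None)),
        "left": (slice(None), slice(0, 1)),
        "right": (slice(None), slice(-1, None)),
    }[wound_side]
    border_labels = np.unique(labels[edge_slice])
    border_labels = border_labels[border_labels != 0]
    if border_labels.size == 0:
        raise ValueError(f"wound not found: no low-texture component on side {wound_side!r}")
    sizes = [(labels == lb).sum() for lb in border_labels]
    mask = labels == border_labels[int(np.argmax(sizes))]
    # the disk-footprint SD filter dilates the textured region by its
    # radius, shrinking the detected wound by the same amount; dilating the
    # component with the same disk undoes that halo
    return dilation(mask, disk(sd_radius))


def geometry_from_masks(masks: Sequence[np.ndarray], wound_side: str,
                        pixel_um: float = 0.7422) -> WoundGeometry:
    """Per-frame, per-column wound-edge coordinates from binary wound masks.

    For a wound on top, the edge in a column is the row index of the first
    monolayer pixel (= number of contiguous wound pixels from the top);
    columns whose wound run spans the whole image have no boundary (NaN).
    """
    edges = []
    for mask in masks:
        m = mask if wound_side in ("top", "bottom") else mask.T
        if wound_side in ("bottom", "right"):
            m = m[::-1]
        # contiguous wound run from the near border, per column
        run = np.argmin(m, axis=0).astype(float)   # first False from the top
        full = np.all(m, axis=0)
        run[full] = np.nan
        # columns with no wound pixel at the border have edge at 0
        run[~m[0]] = 0.0
        n = m.shape[0]
        if wound_side in ("bottom", "right"):
            run = n - run
        edges.append(run)
    return WoundGeometry(wound_side=wound_side, edge_px=edges, pixel_um=pixel_um)


def edge_progression(geometry: WoundGeometry, dt_min: float) -> pd.DataFrame:
    """Leading-edge progression: mean boundary displacement toward the wound.

    Returns a per-frame table with the mean edge coordinate (px), the
    progression since t0 in µm (positive = advancing into the wound) and a
    flag for frames without a measurable boundary.
    """
    rows = []
    edge0 = None
    sign = -1.0 if geometry.wound_side in ("top", "left") else 1.0
    for k, e in enumerate(geometry.edge_px):
        if np.all(np.isnan(e)):
            rows.append({"t_min": k * dt_min, "edge_px": np.nan, "progression_um": np.nan, "ok": False})
            continue
        mean_edge = float(np.nanmean(e))
        if edge0 is None:
            edge0 = mean_edge
        prog = sign * (mean_edge - edge0) * geometry.pixel_um
        rows.append({"t_min": k * dt_min, "edge_px": mean_edge, "progression_um": prog, "ok": True})
    return pd.DataFrame(rows)


def order_parameter(fld: VectorField, geometry: WoundGeometry) -> np.ndarray:
    """Per-vector cosine of the angle to the wound-ward direction.

    1 = coordinated advance straight into the wound, 0 = motion parallel to
    the wound edge.  Zero-magnitude vectors have no direction and are NaN.
    """
    if geometry is None:
        raise ValueError("geometry required for the order parameter")
    n = geometry.normal_toward_wound()
    mag = fld.magnitude()
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (fld.u * n[0] + fld.v * n[1]) / mag
    cosang[mag == 0] = np.nan
    return cosang


@dataclass(frozen=True)
class SpaceTimeMap:
    """Scalar binned by distance-from-front-edge (rows) x time (columns).

    Row 0 is the band touching the front edge; missing (empty) cells are
    NaN with n = 0.
    """

    distance_um: np.ndarray   # band lower edges, µm
    time_min: np.ndarray
    values: np.ndarray        # (n_bands, n_times)
    n: np.ndarray             # contributing vectors per cell

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{t:g}" for t in self.time_min])
        df.insert(0, "distance_um", self.distance_um)
        return df


def build_heatmap(
    fields_per_movie: Sequence[Sequence[VectorField]],
    geometries: Sequence[WoundGeometry],
    cfg: PivConfig,
    scalar: Literal["speed", "order"] = "speed",
    band_um: float | None = None,
    max_distance_um: float | None = None,
    edge_reference: Literal["instantaneous", "t0"] = "instantaneous",
) -> SpaceTimeMap:
    """Space-time map of speed (µm/h) or order parameter, averaged over movies.

    Each vector is assigned its distance from the front edge along the
    wound normal (recomputed per frame by default), the scalar is averaged
    within (distance band x time) cells per movie, then cells are averaged
    across movies.  ``band_um`` defaults to the PIV grid step in µm so each
    vector row is one band.
    """
    if len(fields_per_movie) != len(geometries):
        raise ValueError("one geometry per movie required")
    if band_um is None:
        band_um = cfg.step_px * cfg.pixel_um
    n_times = min(len(f) for f in fields_per_movie)
    vel_scale = cfg.pixel_um * 60.0 / cfg.dt_min

    # distance extent across movies
    if max_distance_um is None:
        max_d = 0.0
        for fields, geom in zip(fields_per_movie, geometries):
            f0 = fields[0]
            coord = f0.grid_y if geom.wound_side in ("top", "bottom") else f0.grid_x
            max_d = max(max_d, float(np.max(coord)) * geom.pixel_um)
        max_distance_um = max_d
    n_bands = max(1, int(np.ceil(max_distance_um / band_um)))
    bands = np.arange(n_bands) * band_um

    per_movie_vals = np.full((len(fields_per_movie), n_bands, n_times), np.nan)
    per_movie_n = np.zeros((len(fields_per_movie), n_bands, n_times), dtype=int)

    for m, (fields, geom) in enumerate(zip(fields_per_movie, geometries)):
        sign = -1.0 if geom.wound_side in ("top", "left") else 1.0
        for t in range(n_times):
            fld = fields[t]
            coord = fld.grid_y if geom.wound_side in ("top", "bottom") else fld.grid_x
            frame_idx = 0 if edge_reference == "t0" else min(t, len(geom.edge_px) - 1)
            edge = geom.mean_edge(frame_idx)
            # distance into the monolayer, µm (positive inside the monolayer)
            dist = sign * (edge - coord) * geom.pixel_um
            if scalar == "speed":
                vals = fld.magnitude() * vel_scale
            else:
                vals = order_parameter(fld, geom)
            ok = fld.valid & (dist >= 0) & ~np.isnan(vals)
            idx = np.floor(dist[ok] / band_um).astype(int)
            keep = idx < n_bands
            idx, vv = idx[keep], vals[ok][keep]
            sums = np.bincount(idx, weights=vv, minlength=n_bands)
            cnts = np.bincount(idx, minlength=n_bands)
            with np.errstate(invalid="ignore"):
                per_movie_vals[m, :, t] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
            per_movie_n[m, :, t] = cnts

    all_nan = np.isnan(per_movie_vals).all(axis=0)
    values = np.where(
        all_nan, np.nan, np.nanmean(np.where(all_nan[None], 0.0, per_movie_vals), axis=0)
    )
    n = per_movie_n.sum(axis=0)
    times = np.arange(n_times) * cfg.dt_min
    return SpaceTimeMap(distance_um=bands, time_min=times, values=values, n=n)


def profile_at_time(stmap: SpaceTimeMap, t_min: float) -> pd.DataFrame:
    """The heat-map column nearest ``t_min``, as a distance-profile table."""
    if t_min < stmap.time_min[0] - 1e-9 or t_min > stmap.time_min[-1] + 1e-9:
        raise ValueError(f"t={t_min} min outside map range "
                         f"[{stmap.time_min[0]}, {stmap.time_min[-1]}]")
    j = int(np.argmin(np.abs(stmap.time_min - t_min)))
    return pd.DataFrame(
        {
            "distance_um": stmap.distance_um,
            "value": stmap.values[:, j],
            "n": stmap.n[:, j],
        }
    )


def write_heatmap(stmap: SpaceTimeMap, csv_path, png_path=None) -> None:
    """Export the map as CSV (rows = distance bands, cols = time) and PNG."""
    stmap.to_dataframe().to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        masked = np.ma.masked_invalid(stmap.values)
        im = ax.imshow(masked, aspect="auto", origin="upper",
                       extent=[stmap.time_min[0], stmap.time_min[-1],
                               stmap.distance_um[-1], stmap.distance_um[0]])
        ax.set_xlabel("time (min)")
        ax.set_ylabel("distance from front edge (µm)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
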