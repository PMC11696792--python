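"""Single-cell migration statistics.

A tracked cell is a sequence of positions sampled at a fixed frame interval
(typically 10 min).  Migration persistence is quantified by the direction
autocorrelation curve — the mean cosine of the angle between displacement
vectors separated by a time lag — and summarised per cell by a two-parameter
fit

    y(t) = (1 - b) * exp(-t / a) + b

where ``a`` (minutes) is the decay constant of directional memory and ``b``
is the long-time plateau: 0 for an unbiased random walker, positive for cells
with a persistent drift direction.  Conditions are compared on the fitted
parameters with a seeded bootstrap test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Track",
    "AutocorrCurve",
    "PersistenceFit",
    "read_tracks",
    "write_tracks",
    "cell_speed",
    "direction_autocorrelation",
    "mean_autocorrelation",
    "fit_persistence",
    "fit_cohort",
    "compare_persistence",
]

#: fitted plateau values closer to 1 than this are treated as the
#: plateau-only degenerate limit (a unidentifiable)
_PLATEAU_EPS = 1e-6


@dataclass(frozen=True)
class Track:
    """One cell's time-stamped 2-D positions at a fixed frame interval.

    Parameters
    ----------
    cell_id : str
        Identifier of the cell.
    t_min : ndarray
        Time stamps in minutes, strictly increasing, uniformly spaced.
    x_um, y_um : ndarray
        Positions in micrometres.
    """

    cell_id: str
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_min, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError(f"track {self.cell_id}: t/x/y must be equal-length 1-D arrays")
        if t.size < 2:
            raise ValueError(f"track {self.cell_id}: needs at least 2 points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"track {self.cell_id}: time stamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"track {self.cell_id}: non-uniform frame interval")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)

    @property
    def dt_min(self) -> float:
        return float(self.t_min[1] - self.t_min[0])

    @property
    def n_points(self) -> int:
        return int(self.t_min.size)

    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive points, shape (n-1, 2)."""
        return np.column_stack([np.diff(self.x_um), np.diff(self.y_um)])


@dataclass(frozen=True)
class AutocorrCurve:
    """Direction autocorrelation: mean cosine per time lag."""

    lags_min: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lags_min", np.asarray(self.lags_min, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, dtype=int))


@dataclass(frozen=True)
class PersistenceFit:
    """Result of the exponential-decay-plus-plateau fit.

    ``a_min`` is the decay constant in minutes (``inf`` in the plateau-only
    degenerate limit), ``b`` the plateau in [-1, 1].
    """

    a_min: float
    b: float
    rss: float
    converged: bool

    def predict(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if not np.isfinite(self.a_min):
            return np.full_like(t, self.b)
        return (1.0 - self.b) * np.exp(-t / self.a_min) + self.b


# ---------------------------------------------------------------------------
# I/O

_TRACK_COLUMNS = ["cell_id", "frame", "t_min", "x_um", "y_um"]


def read_tracks(path_or_buf) -> list[Track]:
    """Read tracks from a CSV with columns cell_id,frame,t_min,x_um,y_um.

    Rows are grouped by ``cell_id`` and sorted by time.  Duplicated
    (cell, frame) rows and non-uniform frame intervals raise ``ValueError``
    naming the offending cell.
    """
    df = pd.read_csv(path_or_buf)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns: {missing}")
    bad = df[df[["t_min", "x_um", "y_um"]].isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()  # header is line 1
        raise ValueError(f"malformed rows at CSV lines {lines}")
    tracks = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("t_min")
        if g["frame"].duplicated().any():
            raise ValueError(f"track {cell_id}: duplicated (cell, frame) rows")
        tracks.append(
            Track(
                cell_id=str(cell_id),
                t_min=g["t_min"].to_numpy(float),
                x_um=g["x_um"].to_numpy(float),
                y_um=g["y_um"].to_numpy(float),
            )
        )
    return tracks


def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write tracks in the canonical CSV schema."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(tr.n_points),
                    "t_min": tr.t_min,
                    "x_um": tr.x_um,
                    "y_um": tr.y_um,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Statistics

def cell_speed(track: Track) -> float:
    """Mean instantaneous speed, µm/min: mean over steps of |Δr|/dt."""
    if track.n_points < 2:
        raise ValueError("speed needs at least 2 points")
    d = np.linalg.norm(track.steps(), axis=1)
    return float(np.mean(d) / track.dt_min)


def direction_autocorrelation(track: Track, max_lag_steps: int | None = None) -> AutocorrCurve:
    """Mean cosine between step vectors separated by ``k`` steps, k=0..max.

    Zero-length steps have no direction: any pair involving one is dropped
    (it does not contribute an angle of 0).  A track whose steps are all
    zero-length is degenerate and rejected.
    """
    steps = track.steps()
    n_steps = steps.shape[0]
    if max_lag_steps is None:
        max_lag_steps = n_steps // 2
    if n_steps < max_lag_steps + 1:
        raise ValueError(
            f"track {track.cell_id}: {n_steps} steps cannot support lag {max_lag_steps}"
        )
    norms = np.linalg.norm(steps, axis=1)
    ok = norms > 0
    if not ok.any():
        raise ValueError(f"track {track.cell_id}: degenerate track (all steps zero-length)")
    unit = np.zeros_like(steps)
    unit[ok] = steps[ok] / norms[ok, None]

    lags = np.arange(max_lag_steps + 1)
    values = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for k in lags:
        if k == 0:
            pair_ok = ok
            cosv = np.ones(n_steps)[pair_ok]
        else:
            pair_ok = ok[:-k] & ok[k:]
            cosv = np.sum(unit[:-k][pair_ok] * unit[k:][pair_ok], axis=1)
        values[k] = np.mean(cosv) if cosv.size else np.nan
        n_pairs[k] = cosv.size
    return AutocorrCurve(lags * track.dt_min, values, n_pairs)


def mean_autocorrelation(curves: Sequence[AutocorrCurve]) -> AutocorrCurve:
    """Pointwise mean of per-cell curves on their common lag grid."""
    if not curves:
        raise ValueError("no curves")
    n_lags = min(c.lags_min.size for c in curves)
    lags = curves[0].lags_min[:n_lags]
    for c in curves:
        if not np.allclose(c.lags_min[:n_lags], lags):
            raise ValueError("curves have incompatible lag grids")
    mat = np.vstack([c.values[:n_lags] for c in curves])
    return AutocorrCurve(lags, np.nanmean(mat, axis=0), np.sum(~np.isnan(mat), axis=0))


def _model(t, a, b):
    return (1.0 - b) * np.exp(-t / a) + b


def fit_persistence(
    curve: AutocorrCurve,
    n_restarts: int = 20,
    seed: int = 0,
) -> PersistenceFit:
    """Least-squares fit of y(t) = (1-b) e^(-t/a) + b to an autocorrelation curve.

    Constraints a > 0, -1 <= b <= 1.  The fit is unweighted and includes
    lag 0 (which the model pins to 1 exactly).  Initialisation uses
    a = duration/4 and b = mean of the last quartile of lags, with up to
    ``n_restarts`` jittered restarts on failure.  A curve uniformly within
    1e-6 of 1 is the plateau-only limit: b = 1, a = inf.
    """
    mask = ~np.isnan(curve.values)
    t = curve.lags_min[mask]
    y = curve.values[mask]
    if np.unique(t).size < 4 or t[0] != 0:
        raise ValueError("fit needs >= 4 distinct lags including lag 0")
    if np.all(np.abs(y - 1.0) < _PLATEAU_EPS):
        return PersistenceFit(a_min=np.inf, b=1.0, rss=float(np.sum((y - 1.0) ** 2)), converged=True)

    t_span = float(t[-1] - t[0])
    a0 = max(t_span / 4.0, 1e-3)
    q = max(1, t.size // 4)
    b0 = float(np.clip(np.mean(y[-q:]), -0.999, 0.999))

    def resid(p):
        return _model(t, p[0], p[1]) - y

    rng = np.random.default_rng(seed)
    best = None
    lo, hi = [1e-6, -1.0], [np.inf, 1.0]
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            p0 = [a0, b0]
        else:
            p0 = [
                a0 * float(np.exp(rng.normal(0.0, 1.0))),
                float(np.clip(b0 + rng.normal(0.0, 0.3), -0.999, 0.999)),
            ]
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
        if sol.success and attempt >= 1:
            break
        if sol.success and attempt == 0:
            break
    if best is None:
        return PersistenceFit(a_min=a0, b=b0, rss=float(np.sum(resid([a0, b0]) ** 2)), converged=False)
    rss, sol = best
    a_hat, b_hat = float(sol.x[0]), float(sol.x[1])
    if b_hat > 1.0 - _PLATEAU_EPS and np.all(np.abs(y - 1.0) < 1e-3):
        return PersistenceFit(a_min=np.inf, b=1.0, rss=rss, converged=True)
    return PersistenceFit(a_min=a_hat, b=b_hat, rss=rss, converged=bool(sol.success))


def fit_cohort(
    tracks: Sequence[Track],
    max_lag_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-cell persistence fits for a cohort of tracks.

    The maximum lag is ``max_lag_frac`` of each track's step count (default
    half, the standard autocorrelation practice).  Returns a DataFrame with
    columns cell_id, a_min, b, rss, converged.
    """
    rows = []
    for tr in tracks:
        n_steps = tr.n_points - 1
        max_lag = max(3, int(n_steps * max_lag_frac))
        curve = direction_autocorrelation(tr, min(max_lag, n_steps - 1))
        fit = fit_persistence(curve)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "a_min": fit.a_min,
                "b": fit.b,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PersistenceComparison:
    effect: float          # mean(b_A) - mean(b_B)
    p_value: float
    effect_a: float        # mean(a_A) - mean(a_B), secondary readout
    p_value_a: float
    n_a: int
    n_b: int


def _bootstrap_p(x: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_boot: int) -> tuple[float, float]:
    """Two-sided bootstrap test of a difference in group means.

    Resamples each group with replacement; the p-value is the (two-sided,
    add-one-corrected) tail probability that the bootstrapped difference
    crosses zero.
    """
    obs = float(np.mean(x) - np.mean(y))
    bx = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    by = rng.choice(y, size=(n_boot, y.size), replace=True).mean(axis=1)
    diffs = bx - by
    p_lo = (np.sum(diffs <= 0) + 1) / (n_boot + 1)
    p_hi = (np.sum(diffs >= 0) + 1) / (n_boot + 1)
    return obs, float(min(1.0, 2.0 * min(p_lo, p_hi)))


def compare_persistence(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> PersistenceComparison:
    """Compare two cohorts of per-cell persistence fits.

    Primary readout: difference in group-mean fitted plateau ``b``;
    secondary: difference in finite decay constants ``a``.  Both use a
    seeded two-sided bootstrap of the difference in means (the original
    study's statistical procedure is unpublished; this is a documented
    substitute, not a reimplementation).
    """
    for name, f in (("A", fits_a), ("B", fits_b)):
        if len(f) < 2:
            raise ValueError(f"group {name} needs >= 2 cells")
        if not np.isfinite(f["b"].to_numpy(float)).any():
            raise ValueError(f"group {name}: all fits degenerate")
    rng = np.random.default_rng(seed)
    ba, bb = fits_a["b"].to_numpy(float), fits_b["b"].to_numpy(float)
    eff_b, p_b = _bootstrap_p(ba, bb, rng, n_boot)
    aa = fits_a["a_min"].to_numpy(float)
    ab = fits_b["a_min"].to_numpy(float)
    aa, ab = aa[np.isfinite(aa)], ab[np.isfinite(ab)]
    if aa.size >= 2 and ab.size >= 2:
        eff_a, p_a = _bootstrap_p(aa, ab, rng, n_boot)
    else:
        eff_a, p_a = math.nan, math.nan
    return PersistenceComparison(eff_b, p_b, eff_a, p_a, len(fits_a), len(fits_b))
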