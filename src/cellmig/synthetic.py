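"""Seeded synthetic-data generators with recorded ground truth.

Every input the analysis layers consume can be generated here with known
parameters, so each downstream stage is testable by parameter recovery:

* persistent random walks (rotational-diffusion heading model) for the
  trajectory/persistence layer,
* textured monolayer movies advected by a known velocity field with a
  cell-free wound region, for the PIV and wound layers,
* 1-D fluorescence profiles with a Gaussian peak at a landmark,
* species-tagged toy MSAs and per-model predictor score tables,
* label-free-quantification tables with bait/control replicates.

All generators take an integer seed and are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .trajectories import Track

__all__ = [
    "TrackSimConfig",
    "gen_tracks",
    "measure_plateau",
    "FieldSpec",
    "MovieSimConfig",
    "SyntheticMovie",
    "gen_movie",
    "ProfileSimConfig",
    "gen_profiles",
    "gen_lfq_table",
    "gen_score_tables",
    "gen_toy_msa",
]


# ---------------------------------------------------------------------------
# Persistent random walks

@dataclass(frozen=True)
class TrackSimConfig:
    """Parameters of the persistent-random-walk track generator.

    The heading follows discrete-time rotational diffusion with angular
    increments N(0, 2*dt/tau), so that with ``bias = 0`` the direction
    autocorrelation is exactly exp(-lag/tau).  A nonzero ``bias`` mixes a
    fixed drift direction into each step, producing a positive plateau.
    Defaults mirror a typical single-cell tracking experiment: frames every
    10 min for 6.5 h, 60 cells.
    """

    n_cells: int = 60
    duration_min: float = 390.0
    dt_min: float = 10.0
    tau_min: float = 60.0
    bias: float = 0.0
    speed_mean: float = 0.5   # µm/min
    speed_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if self.duration_min < 2 * self.dt_min:
            raise ValueError("duration_min must be at least 2*dt_min")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive (use inf for no angular noise)")
        if not (0.0 <= self.bias < 1.0):
            raise ValueError("bias must be in [0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def gen_tracks(cfg: TrackSimConfig) -> tuple[list[Track], dict]:
    """Generate persistent-random-walk tracks; returns (tracks, ground truth).

    Each track has ``duration_min/dt_min`` steps.  With ``tau_min = inf``
    the heading never changes and every track is a straight line.
    """
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.duration_min / cfg.dt_min))
    sigma = 0.0 if np.isinf(cfg.tau_min) else np.sqrt(2.0 * cfg.dt_min / cfg.tau_min)

    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_cells)
    dtheta = rng.normal(0.0, sigma, size=(cfg.n_cells, n_steps)) if sigma > 0 else np.zeros((cfg.n_cells, n_steps))
    theta = theta0[:, None] + np.concatenate(
        [np.zeros((cfg.n_cells, 1)), np.cumsum(dtheta, axis=1)[:, :-1]], axis=1
    )
    speeds = np.maximum(rng.normal(cfg.speed_mean, cfg.speed_sd, size=(cfg.n_cells, n_steps)), 0.0)

    heading = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    drift = np.array([1.0, 0.0])
    mix = (1.0 - cfg.bias) * heading + cfg.bias * drift
    norms = np.linalg.norm(mix, axis=-1, keepdims=True)
    norms[norms == 0] = 1.0
    direction = mix / norms

    disp = direction * (speeds * cfg.dt_min)[:, :, None]
    pos = np.concatenate([np.zeros((cfg.n_cells, 1, 2)), np.cumsum(disp, axis=1)], axis=1)
    t = np.arange(n_steps + 1) * cfg.dt_min

    tracks = [
        Track(cell_id=f"cell_{i:04d}", t_min=t, x_um=pos[i, :, 0], y_um=pos[i, :, 1])
        for i in range(cfg.n_cells)
    ]
    truth = {"tau_min": cfg.tau_min, "bias": cfg.bias, "n_steps": n_steps, "dt_min": cfg.dt_min}
    return tracks, truth


def measure_plateau(bias: float, tau_min: float = 60.0, dt_min: float = 10.0,
                    n_cells: int = 500, n_steps: int = 2000, seed: int = 12345) -> float:
    """Empirical long-lag plateau of the biased heading model.

    The plateau induced by mixing a drift fraction into a stochastic heading
    has no simple closed form; it is measured here by a long simulation
    (mean cosine between steps separated by lags >> tau) and used as ground
    truth for plateau-recovery tests.
    """
    cfg = TrackSimConfig(
        n_cells=n_cells, duration_min=n_steps * dt_min, dt_min=dt_min,
        tau_min=tau_min, bias=bias, seed=seed,
    )
    tracks, _ = gen_tracks(cfg)
    lag = max(10 * int(round(tau_min / dt_min)), 20)
    vals = []
    for tr in tracks:
        steps = tr.steps()
        n = np.linalg.norm(steps, axis=1)
        ok = n > 0
        u = np.zeros_like(steps)
        u[ok] = steps[ok] / n[ok, None]
        pair_ok = ok[:-lag] & ok[lag:]
        vals.append(np.sum(u[:-lag][pair_ok] * u[lag:][pair_ok], axis=1))
    return float(np.mean(np.concatenate(vals)))


# ---------------------------------------------------------------------------
# Monolayer movies

@dataclass(frozen=True)
class FieldSpec:
    """Ground-truth wound-ward velocity profile v(d) = v0 * exp(-d/lambda).

    ``d`` is the distance (µm) from the wound edge into the monolayer;
    ``lambda_um = inf`` gives a uniform field.  Velocities are wound-ward
    (the monolayer advances into the cell-free region).
    """

    v0_umh: float = 9.0
    lambda_um: float = np.inf

    def v_umh(self, d_um):
        d = np.maximum(np.asarray(d_um, dtype=float), 0.0)
        if np.isinf(self.lambda_um):
            return np.full_like(d, self.v0_umh)
        return self.v0_umh * np.exp(-d / self.lambda_um)


@dataclass(frozen=True)
class MovieSimConfig:
    """Parameters of the synthetic wound-healing movie generator.

    The wound is the cell-free strip at the top of the image (low-texture,
    flat intensity); the textured monolayer below it advances wound-ward
    with speed v(d) of ``field_spec``, where d is measured from the current
    wound edge.  ``pixel_um`` defaults to the 10x camera scale at which a
    32-px PIV window spans 23.75 µm.
    """

    height_px: int = 256
    width_px: int = 256
    pixel_um: float = 0.7422
    n_frames: int = 10
    dt_min: float = 10.0
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    texture_grain_px: float = 3.0
    noise_sd: float = 0.0
    wound_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.wound_fraction < 1.0):
            raise ValueError("wound_fraction must be in [0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def v_px_per_frame(self, d_px):
        """Ground-truth displacement magnitude in px/frame at distance d (px)."""
        d_um = np.asarray(d_px, dtype=float) * self.pixel_um
        return self.field_spec.v_umh(d_um) / 60.0 * self.dt_min / self.pixel_um


@dataclass(frozen=True)
class SyntheticMovie:
    """A generated movie plus its ground truth.

    ``frames`` is the uint16 stack actually analysed; ``edge_rows`` the true
    wound-edge row per frame.  ``displacement_rows(k)`` gives the planted
    per-row wound-ward displacement (px/frame, negative = toward the top)
    between frames k and k+1.
    """

    frames: np.ndarray            # (n_frames, H, W) uint16
    config: MovieSimConfig
    edge_rows: np.ndarray         # float, per frame

    def displacement_rows(self, k: int) -> np.ndarray:
        cfg = self.config
        y = np.arange(cfg.height_px, dtype=float)
        d = np.maximum(y - self.edge_rows[k], 0.0)
        return -cfg.v_px_per_frame(d)

    def true_displacement_at(self, k: int, y_px: np.ndarray) -> np.ndarray:
        """Planted (u, v) displacement at image rows ``y_px`` for pair (k, k+1)."""
        d = np.maximum(np.asarray(y_px, dtype=float) - self.edge_rows[k], 0.0)
        v = -self.config.v_px_per_frame(d)
        return np.column_stack([np.zeros_like(v), v])


def gen_movie(cfg: MovieSimConfig) -> SyntheticMovie:
    """Generate a textured monolayer movie advected by the ground-truth field.

    Frame k+1 is frame k backward-warped by the per-frame displacement field
    (cubic spline), with fresh per-frame noise added on top of the noiseless
    advected image.  The wound edge advances wound-ward at v(0) per frame.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height_px, cfg.width_px

    texture = gaussian_filter(rng.standard_normal((H, W)), cfg.texture_grain_px)
    texture = texture / max(texture.std(), 1e-12)
    base = 1000.0 + 400.0 * texture  # counts; wound region is flat 200

    edge0 = cfg.wound_fraction * H
    yy = np.arange(H, dtype=float)[:, None]
    img = np.where(yy < edge0, 200.0, base)

    v0_px = float(cfg.v_px_per_frame(0.0))
    if v0_px > 16.0:
        warnings.warn(
            f"per-frame displacement {v0_px:.1f} px exceeds half a 32-px PIV window; "
            "correlation will alias", stacklevel=2
        )

    cols = np.broadcast_to(np.arange(W, dtype=float), (H, W))
    edge_rows = np.empty(cfg.n_frames)
    noiseless = [img]
    base = img
    y_grid = yy[:, 0]
    # cumulative backward map M_k: frame_k(y) = base(M_k(y)); composing the
    # 1-D maps analytically keeps every rendered frame one interpolation
    # away from the sharp base image (no accumulated blur)
    back_map = y_grid.copy()
    edge = edge0
    edge_rows[0] = edge
    for k in range(1, cfg.n_frames):
        d = np.maximum(y_grid - edge, 0.0)
        shift = cfg.v_px_per_frame(d)  # content moves toward smaller y
        back_map = np.interp(y_grid + shift, y_grid, back_map,
                             left=back_map[0], right=None)
        back_map = np.minimum(back_map, y_grid[-1])
        rows = np.broadcast_to(back_map[:, None], (H, W))
        img = map_coordinates(base, [rows, cols], order=3, mode="nearest")
        noiseless.append(img)
        edge = edge - v0_px
        edge_rows[k] = edge

    stack = np.stack(noiseless)
    if cfg.noise_sd > 0:
        stack = stack + rng.normal(0.0, cfg.noise_sd, size=stack.shape)
    frames = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    return SyntheticMovie(frames=frames, config=cfg, edge_rows=edge_rows)


def write_movie(movie: SyntheticMovie, tiff_path, truth_json_path=None) -> None:
    """Write the stack as a multi-page 16-bit TIFF plus a truth sidecar JSON."""
    import tifffile

    tifffile.imwrite(tiff_path, movie.frames)
    if truth_json_path is not None:
        truth = {
            "edge_rows": movie.edge_rows.tolist(),
            "config": {k: (None if isinstance(v, FieldSpec) else v)
                       for k, v in asdict(movie.config).items()},
            "field_spec": asdict(movie.config.field_spec),
        }
        with open(truth_json_path, "w") as fh:
            json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------------
# Fluorescence line profiles

@dataclass(frozen=True)
class ProfileSimConfig:
    """Gaussian-peak-on-background model of a fluorescence line scan."""

    length_um: float = 10.0
    step_um: float = 0.1
    peak_pos_um: float = 5.0
    peak_sigma_um: float = 0.5
    peak_amp: float = 100.0
    background: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        n = self.length_um / self.step_um
        if abs(n - round(n)) > 1e-9:
            raise ValueError("length_um must be an integral multiple of step_um")
        if self.peak_amp < 0:
            raise ValueError("peak_amp must be >= 0")

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(int(round(self.length_um / self.step_um)) + 1) * self.step_um

    def noiseless(self) -> np.ndarray:
        x = self.positions_um
        return self.background + self.peak_amp * np.exp(
            -((x - self.peak_pos_um) ** 2) / (2.0 * self.peak_sigma_um**2)
        )


def gen_profiles(cfg: ProfileSimConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n noisy realisations of the profile model; returns (positions_um, (n, len))."""
    rng = np.random.default_rng(cfg.seed)
    clean = cfg.noiseless()
    out = clean[None, :] + rng.normal(0.0, cfg.noise_sd, size=(n, clean.size))
    return cfg.positions_um, out


# ---------------------------------------------------------------------------
# LFQ tables (bait/control pulldowns)

def gen_lfq_table(
    n_true: int,
    n_decoy: int,
    n_bait_reps: int = 3,
    n_ctrl_reps: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Synthetic label-free-quantification table with planted partners.

    True partners satisfy the specificity rules (detected in >= 2 bait
    replicates, absent from every control, >= 2 razor/unique peptides);
    each decoy violates exactly one rule: a control detection, too few bait
    detections, or a single peptide.  Returns the table and the set of true
    partner ids.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: set[str] = set()
    min_bait = 2

    def intensities(mask):
        vals = np.zeros(len(mask))
        vals[mask] = 10 ** rng.uniform(6, 9, size=int(np.sum(mask)))
        return vals

    for i in range(n_true):
        pid = f"TRUE_{i:03d}"
        truth.add(pid)
        n_det = int(rng.integers(min_bait, n_bait_reps + 1))
        mask = np.zeros(n_bait_reps, dtype=bool)
        mask[rng.choice(n_bait_reps, size=n_det, replace=False)] = True
        rows.append((pid, int(rng.integers(2, 30)), intensities(mask), np.zeros(n_ctrl_reps)))

    modes = rng.integers(0, 3, size=n_decoy)
    for i in range(n_decoy):
        pid = f"DECOY_{i:03d}"
        bait_mask = np.zeros(n_bait_reps, dtype=bool)
        ctrl_mask = np.zeros(n_ctrl_reps, dtype=bool)
        peptides = int(rng.integers(2, 30))
        if modes[i] == 0:  # seen in a control
            bait_mask[rng.choice(n_bait_reps, size=n_bait_reps, replace=False)[:min_bait]] = True
            ctrl_mask[rng.integers(0, n_ctrl_reps)] = True
        elif modes[i] == 1:  # too few bait detections
            if rng.random() < 0.7:
                bait_mask[rng.integers(0, n_bait_reps)] = True
        else:  # single peptide
            bait_mask[:] = True
            peptides = 1
        rows.append((pid, peptides, intensities(bait_mask), intensities(ctrl_mask)))

    data = {"protein_id": [r[0] for r in rows], "peptides": [r[1] for r in rows]}
    for j in range(n_bait_reps):
        data[f"bait_{j + 1}"] = [r[2][j] for r in rows]
    for j in range(n_ctrl_reps):
        data[f"ctrl_{j + 1}"] = [r[3][j] for r in rows]
    return pd.DataFrame(data), truth


# ---------------------------------------------------------------------------
# Predictor score tables and toy MSAs

def gen_score_tables(n_candidates: int, n_models: int = 5, seed: int = 0) -> list[dict]:
    """Random per-model pLDDT/pTM/ipTM score sets for screen/ranking tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_candidates):
        models = [
            {
                "plddt": float(rng.uniform(0.3, 1.0)),
                "ptm": float(rng.uniform(0.1, 1.0)),
                "iptm": float(rng.uniform(0.1, 1.0)),
            }
            for _ in range(n_models)
        ]
        out.append({"bait": f"frag_{i:02d}", "prey": f"prey_{i:02d}", "models": models})
    return out


def gen_toy_msa(species: Sequence[str], width: int = 20, seed: int = 0,
                query_id: str = "query") -> list[tuple[str, str, str]]:
    """Toy aligned MSA rows as (row_id, species_tag, aligned_seq).

    The query (first row, species tag of the first entry) is random protein
    sequence; members are mutated copies so identity-to-query stays high.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    query = alphabet[rng.integers(0, 20, size=width)]
    rows = [(query_id, "query", "".join(query))]
    for sp in species:
        seq = query.copy()
        n_mut = int(rng.integers(1, max(2, width // 5)))
        idx = rng.choice(width, size=n_mut, replace=False)
        seq[idx] = alphabet[rng.integers(0, 20, size=n_mut)]
        rows.append((f"{query_id}_{sp}", sp, "".join(seq)))
    return rows
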