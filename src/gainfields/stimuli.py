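"""Population-coded stimuli for visuospatial transformation learning.

The sensory world of the simulations is a small 2-D visual space measured in
degrees of visual angle.  Three kinds of signals are encoded:

* a **retinotopic map**: a 17x17 grid of units with Gaussian tuning
  (sigma = 4 deg) representing the position of a visual stimulus;
* four **postural maps**: 17 sigmoid units each (steepness 0.125),
  representing the horizontal and vertical positions of the eye and of a
  generic effector (e.g. the hand);
* a **motor map**: a 25x25 grid of Gaussian-tuned units (sigma = 6 deg)
  representing the target position in effector-centered coordinates.

The target position follows the standard effector-centered coordinate
transform ``target = retinal + eye - effector``.  A balanced dataset is
produced by enumerating the full factorial grid of retinal, eye and effector
positions, keeping combinations whose target falls on the representable
motor grid, and drawing an equal number of patterns per target location.

Coordinate and storage conventions (fixed so receptive-field images are
unambiguous): x is horizontal, y vertical, origin at fixation; 2-D maps are
stored row-major with y as the slow (row) axis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TASKS",
    "SpaceConfig",
    "Pattern",
    "Dataset",
    "encode_retinal",
    "encode_postural",
    "encode_motor",
    "compute_target",
    "generate_dataset",
    "input_slices",
    "input_size",
]

#: Learning settings: unsupervised without the motor program in the input (A),
#: unsupervised with the motor program appended to the input (B), and the
#: supervised input->motor mapping (C).
TASKS = ("no_transformation", "with_transformation", "supervised")

POSITION_COLUMNS = (
    "retinal_x", "retinal_y", "eye_x", "eye_y",
    "effector_x", "effector_y", "target_x", "target_y",
)


@dataclass(frozen=True)
class SpaceConfig:
    """Geometry and tuning parameters of the encoded space.

    The retinal and motor grids are wider than the range of stimulus and
    target positions: unit centers tile -24..+24 deg (retinal, 17 per axis)
    and -36..+36 deg (motor, 25 per axis) in 3 deg steps, while stimuli and
    targets are confined to -9..+9 deg, so Gaussian tails of peripheral
    stimuli remain well inside the map.  Postural thresholds tile -24..+24,
    covering the +-18 deg postural range with margin.
    """

    retinal_grid_size: int = 17
    motor_grid_size: int = 25
    postural_units: int = 17
    retinal_sigma: float = 4.0
    motor_sigma: float = 6.0
    postural_steepness: float = 0.125
    grid_spacing: float = 3.0
    stimulus_extent: float = 9.0
    postural_extent: float = 18.0

    def __post_init__(self) -> None:
        if self.retinal_sigma <= 0 or self.motor_sigma <= 0:
            raise ValueError("tuning widths must be positive")
        if self.postural_steepness <= 0:
            raise ValueError("postural steepness must be positive")
        if min(self.retinal_grid_size, self.motor_grid_size,
               self.postural_units) < 1:
            raise ValueError("grid sizes must be positive")

    # ----- derived geometry -------------------------------------------------
    @property
    def stimulus_positions(self) -> np.ndarray:
        """Admissible stimulus (and target) positions per axis, degrees."""
        return self._axis(self.stimulus_extent)

    @property
    def postural_positions(self) -> np.ndarray:
        """Admissible eye/effector positions per axis, degrees."""
        return self._axis(self.postural_extent)

    @property
    def retinal_centers(self) -> np.ndarray:
        """Retinal unit centers per axis (17 values, -24..+24)."""
        return self._centered_axis(self.retinal_grid_size)

    @property
    def motor_centers(self) -> np.ndarray:
        """Motor unit centers per axis (25 values, -36..+36)."""
        return self._centered_axis(self.motor_grid_size)

    @property
    def postural_thresholds(self) -> np.ndarray:
        """Sigmoid thresholds of the 17 postural units (-24..+24)."""
        return self._centered_axis(self.postural_units)

    def _axis(self, extent: float) -> np.ndarray:
        n = int(round(2 * extent / self.grid_spacing)) + 1
        return -extent + self.grid_spacing * np.arange(n)

    def _centered_axis(self, n: int) -> np.ndarray:
        return self.grid_spacing * (np.arange(n) - (n - 1) / 2.0)

    def grid_centers_2d(self, which: str) -> np.ndarray:
        """(n*n, 2) array of unit centers, y-major order."""
        axis = self.retinal_centers if which == "retinal" else self.motor_centers
        yy, xx = np.meshgrid(axis, axis, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    # ----- config file round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SpaceConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _check_range(pos: np.ndarray, lo: float, hi: float, what: str) -> None:
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError(
            f"{what} position outside the representable range [{lo}, {hi}]"
        )


def encode_retinal(pos, cfg: SpaceConfig | None = None) -> np.ndarray:
    """Encode 2-D position(s) on the retinotopic Gaussian population map.

    Parameters
    ----------
    pos : array-like, shape (2,) or (n, 2)
        Position(s) in degrees.
    cfg : SpaceConfig, optional

    Returns
    -------
    ndarray, shape (289,) or (n, 289)
        Unit ``i`` carries ``exp(-||pos - center_i||^2 / (2 sigma^2))``.
    """
    cfg = cfg or SpaceConfig()
    return _encode_gaussian(pos, cfg.grid_centers_2d("retinal"),
                            cfg.retinal_sigma, cfg.stimulus_extent, "stimulus")


def encode_motor(target, cfg: SpaceConfig | None = None) -> np.ndarray:
    """Encode target position(s) on the 25x25 motor map (sigma = 6 deg)."""
    cfg = cfg or SpaceConfig()
    return _encode_gaussian(target, cfg.grid_centers_2d("motor"),
                            cfg.motor_sigma, cfg.stimulus_extent, "target")


def _encode_gaussian(pos, centers, sigma, extent, what) -> np.ndarray:
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    if pos.shape[-1] != 2:
        raise ValueError(f"{what} positions must be 2-d")
    _check_range(pos, -extent, extent, what)
    sq = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    act = np.exp(-sq / (2.0 * sigma ** 2))
    return act[0] if single else act


def encode_postural(pos, cfg: SpaceConfig | None = None) -> np.ndarray:
    """Encode scalar postural position(s) on a 17-unit sigmoid map.

    Unit ``i`` carries ``1 / (1 + exp(-0.125 (pos - theta_i)))``, strictly
    increasing in ``pos``.
    """
    cfg = cfg or SpaceConfig()
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 0
    pos = np.atleast_1d(pos)
    _check_range(pos, -cfg.postural_extent, cfg.postural_extent, "postural")
    z = cfg.postural_steepness * (pos[:, None] - cfg.postural_thresholds[None, :])
    act = 1.0 / (1.0 + np.exp(-z))
    return act[0] if single else act


def compute_target(retinal_pos, eye_pos, effector_pos) -> np.ndarray:
    """Effector-centered target position: ``retinal + eye - effector``."""
    return (np.asarray(retinal_pos, dtype=float)
            + np.asarray(eye_pos, dtype=float)
            - np.asarray(effector_pos, dtype=float))


def input_slices(cfg: SpaceConfig | None = None,
                 task: str = "no_transformation") -> dict[str, slice]:
    """Section layout of a concatenated input vector for a given task."""
    cfg = cfg or SpaceConfig()
    r = cfg.retinal_grid_size ** 2
    p = cfg.postural_units
    out = {
        "retinal": slice(0, r),
        "eye_x": slice(r, r + p),
        "eye_y": slice(r + p, r + 2 * p),
        "effector_x": slice(r + 2 * p, r + 3 * p),
        "effector_y": slice(r + 3 * p, r + 4 * p),
    }
    if task == "with_transformation":
        m = cfg.motor_grid_size ** 2
        out["motor"] = slice(r + 4 * p, r + 4 * p + m)
    return out


def input_size(cfg: SpaceConfig | None = None,
               task: str = "no_transformation") -> int:
    slices = input_slices(cfg, task)
    return max(s.stop for s in slices.values())


@dataclass(frozen=True)
class Pattern:
    """One stimulus with its encodings and ground-truth positions."""

    retinal_map: np.ndarray
    postural_vectors: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    motor_map: np.ndarray
    retinal_pos: np.ndarray
    eye_pos: np.ndarray
    effector_pos: np.ndarray
    target_pos: np.ndarray

    @property
    def sensory_input(self) -> np.ndarray:
        """Concatenated retinal + postural sections (length 357)."""
        return np.concatenate([self.retinal_map, *self.postural_vectors])


class Dataset:
    """Balanced, split collection of patterns for one learning task.

    Encodings are stored as dense arrays (rows = patterns); `Pattern` views
    are materialized on demand.  ``sensory`` holds the retinal + postural
    sections (357 columns); ``motor`` holds the motor-map target (625).
    """

    def __init__(self, config: SpaceConfig, task: str, seed: int,
                 train_sensory, train_motor, train_positions,
                 test_sensory, test_motor, test_positions):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        self.config = config
        self.task = task
        self.seed = int(seed)
        self._data = {
            "train": (np.asarray(train_sensory), np.asarray(train_motor),
                      np.asarray(train_positions)),
            "test": (np.asarray(test_sensory), np.asarray(test_motor),
                     np.asarray(test_positions)),
        }

    # ----- access -----------------------------------------------------------
    @property
    def n_train(self) -> int:
        return len(self._data["train"][0])

    @property
    def n_test(self) -> int:
        return len(self._data["test"][0])

    @property
    def input_dim(self) -> int:
        return input_size(self.config, self.task)

    def sensory(self, split: str) -> np.ndarray:
        return self._data[split][0]

    def motor(self, split: str) -> np.ndarray:
        return self._data[split][1]

    def positions(self, split: str) -> pd.DataFrame:
        return pd.DataFrame(self._data[split][2], columns=POSITION_COLUMNS)

    def target_positions(self, split: str) -> np.ndarray:
        return self._data[split][2][:, 6:8]

    def inputs(self, split: str) -> np.ndarray:
        """Input matrix presented during (unsupervised) training.

        For the ``with_transformation`` task the motor map is part of the
        input (982 columns); otherwise the sensory sections alone (357).
        """
        sens, motor, _ = self._data[split]
        if self.task == "with_transformation":
            return np.hstack([sens, motor])
        return sens

    def probe_inputs(self, split: str) -> np.ndarray:
        """Inputs used when probing hidden neurons and training the read-out.

        The motor section, when present, is held at zero: the network must
        carry the target location in its hidden code rather than copy it
        from the input.
        """
        sens, motor, _ = self._data[split]
        if self.task == "with_transformation":
            return np.hstack([sens, np.zeros_like(motor)])
        return sens

    def patterns(self, split: str) -> Iterator[Pattern]:
        cfg = self.config
        slices = input_slices(cfg, "no_transformation")
        sens, motor, pos = self._data[split]
        for i in range(len(sens)):
            yield Pattern(
                retinal_map=sens[i, slices["retinal"]],
                postural_vectors=tuple(
                    sens[i, slices[k]]
                    for k in ("eye_x", "eye_y", "effector_x", "effector_y")),
                motor_map=motor[i],
                retinal_pos=pos[i, 0:2], eye_pos=pos[i, 2:4],
                effector_pos=pos[i, 4:6], target_pos=pos[i, 6:8],
            )

    # ----- serialization ----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["task"] = self.task
            fh.attrs["seed"] = self.seed
            fh.attrs["config"] = yaml.safe_dump(asdict(self.config))
            fh.attrs["config_hash"] = self.config.digest()
            for split in ("train", "test"):
                grp = fh.create_group(split)
                sens, motor, pos = self._data[split]
                grp.create_dataset("sensory", data=sens, compression="gzip")
                grp.create_dataset("motor", data=motor, compression="gzip")
                grp.create_dataset("positions", data=pos)

    @classmethod
    def load(cls, path) -> "Dataset":
        with h5py.File(path, "r") as fh:
            cfg = SpaceConfig(**yaml.safe_load(fh.attrs["config"]))
            parts = {}
            for split in ("train", "test"):
                grp = fh[split]
                parts[split] = (grp["sensory"][...], grp["motor"][...],
                                grp["positions"][...])
            return cls(cfg, fh.attrs["task"], int(fh.attrs["seed"]),
                       *parts["train"], *parts["test"])

    def positions_to_csv(self, path_prefix) -> None:
        for split in ("train", "test"):
            self.positions(split).to_csv(f"{path_prefix}_{split}.csv",
                                         index=False)


def _balanced_pool(cfg: SpaceConfig, seed: int,
                   patterns_per_target: int | None) -> np.ndarray:
    """Enumerate the factorial position grid and balance by target cell.

    Returns an (N, 8) float array of positions (columns as
    ``POSITION_COLUMNS``) with every target location equally represented.
    """
    stim = cfg.stimulus_positions
    post = cfg.postural_positions
    grids = np.meshgrid(stim, stim, post, post, post, post, indexing="ij")
    combos = np.column_stack([g.ravel() for g in grids])
    rx, ry, ex, ey, fx, fy = combos.T
    tx = rx + ex - fx
    ty = ry + ey - fy
    ext = cfg.stimulus_extent
    valid = (np.abs(tx) <= ext) & (np.abs(ty) <= ext)
    combos = combos[valid]
    tx, ty = tx[valid], ty[valid]

    n_cells = len(stim) ** 2
    if patterns_per_target is None:
        patterns_per_target = 28880 // n_cells  # 589 per cell, 28,861 total
    cell = (np.searchsorted(stim, tx) * len(stim) + np.searchsorted(stim, ty))
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in range(n_cells):
        idx = np.flatnonzero(cell == c)
        if len(idx) < patterns_per_target:
            raise ValueError(
                f"target cell {c} has only {len(idx)} combinations, "
                f"fewer than the requested {patterns_per_target} per cell")
        keep.append(rng.choice(idx, size=patterns_per_target, replace=False))
    sel = np.concatenate(keep)
    positions = np.column_stack([combos[sel], tx[sel], ty[sel]])
    return positions


def _encode_positions(cfg: SpaceConfig, positions: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized encoding via lookup tables over the few distinct values."""
    stim = cfg.stimulus_positions
    post = cfg.postural_positions
    # distinct retinal / motor maps: one per 2-D grid position (49 each)
    pos2d = np.column_stack([g.ravel() for g in
                             np.meshgrid(stim, stim, indexing="ij")])
    retinal_lut = encode_retinal(pos2d, cfg)
    motor_lut = encode_motor(pos2d, cfg)
    postural_lut = encode_postural(post, cfg)

    def idx2d(x, y):
        return np.searchsorted(stim, x) * len(stim) + np.searchsorted(stim, y)

    rx, ry, ex, ey, fx, fy, tx, ty = positions.T
    sensory = np.hstack([
        retinal_lut[idx2d(rx, ry)],
        postural_lut[np.searchsorted(post, ex)],
        postural_lut[np.searchsorted(post, ey)],
        postural_lut[np.searchsorted(post, fx)],
        postural_lut[np.searchsorted(post, fy)],
    ])
    motor = motor_lut[idx2d(tx, ty)]
    return sensory, motor


def generate_dataset(cfg: SpaceConfig | None = None,
                     task: str = "no_transformation",
                     seed: int = 0,
                     train_size: int = 20000,
                     test_size: int | None = None,
                     patterns_per_target: int | None = None) -> Dataset:
    """Generate the balanced, split stimulus dataset.

    The full factorial grid of retinal (7x7), eye (13x13) and effector
    (13x13) positions is enumerated; combinations whose target leaves the
    representable motor range are dropped; the remainder is balanced to an
    equal count per target cell (by default 589 per cell, 28,861 patterns,
    approximating the nominal 28,880 which is not divisible by 49) and split
    at random into train and test sets.

    Parameters
    ----------
    task : {"no_transformation", "with_transformation", "supervised"}
    seed : int
        Controls both the balancing draw and the train/test split.
    train_size, test_size : int
        ``test_size=None`` uses the entire remainder of the balanced pool.
    patterns_per_target : int, optional
        Override the per-cell count (smaller values give scaled-down pools).
    """
    cfg = cfg or SpaceConfig()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if train_size < 1:
        raise ValueError("train_size must be at least 1")
    positions = _balanced_pool(cfg, seed, patterns_per_target)
    n_pool = len(positions)
    if test_size is None:
        test_size = max(n_pool - train_size, 0)
    if train_size + test_size > n_pool:
        raise ValueError(
            f"requested {train_size}+{test_size} patterns but the balanced "
            f"pool holds only {n_pool}")
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n_pool)
    tr = order[:train_size]
    te = order[train_size:train_size + test_size]
    sens_tr, motor_tr = _encode_positions(cfg, positions[tr])
    sens_te, motor_te = _encode_positions(cfg, positions[te])
    return Dataset(cfg, task, seed,
                   sens_tr, motor_tr, positions[tr],
                   sens_te, motor_te, positions[te])
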