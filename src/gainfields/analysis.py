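"""Single-neuron analyses of trained hidden layers.

Implements the study's neuron-level measures:

* **activity fraction** ``a = (sum r_i / n)^2 / sum(r_i^2 / n)``, the
  classic sparseness statistic (1 for uniform firing, 1/n for one-hot),
  applied per neuron across stimuli (single-neuron / lifetime sparseness)
  and per stimulus across the layer (population sparseness);
* **visual-neuron selection**: a neuron is "visual" if its peak response
  with visual input differs by more than 10% from its peak response to
  postural input alone;
* **gain-modulation indices (GMI)**: from the input combination maximizing
  a neuron's response, each postural variable is swept in turn and the
  modulation depth ``(max - min) / max`` recorded, one GMI per variable
  (eye-x, eye-y, effector-x, effector-y);
* **gain-field classification** into pure-visual / eye-only /
  effector-only / multiple, thresholding the per-signal GMI at 0.5;
* **receptive fields**: the retinal slice of a hidden neuron's incoming
  weights as a 17x17 patch.

Probing evaluates neurons over the factorial grid of 49 retinal and 13^4
postural positions (motor section, when present, held at zero).  For the
hidden layers built here -- a sigmoid over an affine map -- the grid is
separable: the pre-activation is a sum of independent per-section terms,
so the exact grid maximum is found from per-section maxima without
enumerating the ~1.4M combinations.  Arbitrary probe callables are handled
by batched brute-force enumeration (optionally stride-subsampled), which
also serves as the oracle for the separable shortcut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import (SpaceConfig, encode_postural, encode_retinal,
                      input_size, input_slices)

__all__ = [
    "activity_fraction",
    "single_neuron_sparseness",
    "population_sparseness",
    "SparsenessReport",
    "sparseness_report",
    "NeuronProfile",
    "GainFieldDistribution",
    "GainFieldAnalysis",
    "select_visual_neurons",
    "compute_gmi",
    "classify_gain_fields",
    "analyze_gain_fields",
    "receptive_field",
    "render_receptive_fields",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("pure_visual", "eye_only", "effector_only", "multiple")
POSTURAL_VARS = ("eye_x", "eye_y", "effector_x", "effector_y")

#: Relative change of peak response that qualifies a neuron as visual.
VISUAL_THRESHOLD = 0.10
#: Absolute fallback when the no-visual response is (numerically) zero.
VISUAL_ABSOLUTE_FALLBACK = 0.01


# --------------------------------------------------------------------------
# sparseness
# --------------------------------------------------------------------------

def activity_fraction(rates) -> float:
    """Activity fraction ``(sum r/n)^2 / sum(r^2/n)`` of a rate vector.

    Bounded in ``[1/n, 1]``: 1 for uniform rates, 1/n for a one-hot vector.
    Invariant to positive rescaling.  Rejects negative rates and all-zero
    vectors.
    """
    r = np.asarray(rates, dtype=float)
    if r.ndim != 1 or len(r) < 1:
        raise ValueError("rates must be a non-empty 1-d vector")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    mean_sq = (r ** 2).mean()
    if mean_sq == 0.0:
        raise ValueError("activity fraction undefined for an all-zero vector")
    return float(r.mean() ** 2 / mean_sq)


def _fraction_along(acts: np.ndarray, axis: int) -> tuple[float, int]:
    """Mean activity fraction along an axis, excluding silent slices."""
    acts = np.asarray(acts, dtype=float)
    if acts.ndim != 2:
        raise ValueError("activations must be 2-d (stimuli x neurons)")
    if np.any(acts < 0):
        raise ValueError("activations must be non-negative")
    mean = acts.mean(axis=axis)
    mean_sq = (acts ** 2).mean(axis=axis)
    alive = mean_sq > 0.0
    n_silent = int((~alive).sum())
    if not alive.any():
        raise ValueError("all slices are silent; sparseness undefined")
    return float((mean[alive] ** 2 / mean_sq[alive]).mean()), n_silent


def single_neuron_sparseness(activations) -> float:
    """Mean activity fraction per neuron across stimuli (lifetime sparseness).

    Silent neurons (zero on every stimulus) are excluded; the count is
    logged.
    """
    value, n_silent = _fraction_along(activations, axis=0)
    if n_silent:
        logger.info("single-neuron sparseness: excluded %d silent neurons",
                    n_silent)
    return value


def population_sparseness(activations) -> float:
    """Mean activity fraction per stimulus across the hidden layer."""
    value, n_silent = _fraction_along(activations, axis=1)
    if n_silent:
        logger.info("population sparseness: excluded %d silent stimuli",
                    n_silent)
    return value


@dataclass(frozen=True)
class SparsenessReport:
    single_neuron: float
    population: float
    n_silent_neurons: int
    n_stimuli: int
    n_neurons: int


def sparseness_report(activations) -> SparsenessReport:
    """Both sparseness indices of a (stimuli x neurons) activation matrix."""
    sn, n_silent = _fraction_along(activations, axis=0)
    pop, _ = _fraction_along(activations, axis=1)
    acts = np.asarray(activations)
    return SparsenessReport(single_neuron=sn, population=pop,
                            n_silent_neurons=n_silent,
                            n_stimuli=acts.shape[0], n_neurons=acts.shape[1])


# --------------------------------------------------------------------------
# probe grids
# --------------------------------------------------------------------------

class _AffineProbe:
    """Exact factorial-grid probing of a sigmoid-over-affine hidden layer.

    The pre-activation of an input assembled from independent sections is
    the sum of per-section contributions, so grid maxima decompose into
    per-section maxima (the sigmoid is monotonic).
    """

    def __init__(self, weight: np.ndarray, bias: np.ndarray,
                 cfg: SpaceConfig, task: str):
        self.cfg = cfg
        self.task = task
        slices = input_slices(cfg, task)
        stim = cfg.stimulus_positions
        pos2d = np.column_stack([g.ravel() for g in
                                 np.meshgrid(stim, stim, indexing="ij")])
        retinal_lut = encode_retinal(pos2d, cfg)          # (49, 289)
        postural_lut = encode_postural(cfg.postural_positions, cfg)  # (13,17)
        self.n_retinal = len(pos2d)
        self.n_postural = len(cfg.postural_positions)
        self.bias = np.asarray(bias, dtype=float)
        self.A_retinal = retinal_lut @ weight[:, slices["retinal"]].T  # 49xH
        self.A_post = [postural_lut @ weight[:, slices[v]].T          # 13xH
                       for v in POSTURAL_VARS]
        self.n_neurons = weight.shape[0]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def max_without_visual(self):
        """Peak response over the 13^4 postures with the visual input zeroed."""
        idx = np.stack([A.argmax(axis=0) for A in self.A_post], axis=1)
        pre = self.bias + sum(A.max(axis=0) for A in self.A_post)
        return self._sigmoid(pre), idx

    def _postural_pre(self, posture_idx: np.ndarray) -> np.ndarray:
        cols = np.arange(self.n_neurons)
        return self.bias + sum(A[posture_idx[:, k], cols]
                               for k, A in enumerate(self.A_post))

    def max_with_visual(self, posture_idx: np.ndarray):
        """Peak over the 49 retinal positions at per-neuron fixed postures."""
        base = self._postural_pre(posture_idx)
        pre = base[None, :] + self.A_retinal          # 49 x H
        r_idx = pre.argmax(axis=0)
        return self._sigmoid(pre.max(axis=0)), r_idx

    def max_full(self):
        """Grid-wide maximizing combination (separable: exact)."""
        act_no, posture_idx = self.max_without_visual()
        act, r_idx = self.max_with_visual(posture_idx)
        return act, r_idx, posture_idx

    def sweep(self, var: int, retinal_idx: np.ndarray,
              posture_idx: np.ndarray) -> np.ndarray:
        """Responses (13 x H) sweeping one postural variable, rest fixed."""
        cols = np.arange(self.n_neurons)
        base = self.bias + self.A_retinal[retinal_idx, cols] + sum(
            A[posture_idx[:, k], cols]
            for k, A in enumerate(self.A_post) if k != var)
        return self._sigmoid(base[None, :] + self.A_post[var])


class _CallableProbe:
    """Brute-force factorial-grid probing of an arbitrary probe function.

    ``probe(inputs)`` maps an (n, D) input matrix to (n, H) activations.
    ``stride`` subsamples the postural grid (non-canonical quick mode).
    """

    def __init__(self, probe, cfg: SpaceConfig, task: str, stride: int = 1,
                 batch_size: int = 8192):
        self.probe = probe
        self.cfg = cfg
        self.task = task
        self.slices = input_slices(cfg, task)
        self.input_dim = input_size(cfg, task)
        stim = cfg.stimulus_positions
        pos2d = np.column_stack([g.ravel() for g in
                                 np.meshgrid(stim, stim, indexing="ij")])
        self.retinal_lut = encode_retinal(pos2d, cfg)
        post = cfg.postural_positions
        self.post_sel = np.arange(0, len(post), stride)
        self.postural_lut = encode_postural(post, cfg)
        self.n_retinal = len(pos2d)
        self.n_postural = len(post)
        self.batch_size = batch_size
        self.n_neurons = np.asarray(
            probe(np.zeros((1, self.input_dim)))).shape[1]

    def _assemble(self, retinal_idx, posture_idx) -> np.ndarray:
        """Input matrix for aligned retinal (or None) and posture indices."""
        n = len(posture_idx)
        X = np.zeros((n, self.input_dim))
        if retinal_idx is not None:
            X[:, self.slices["retinal"]] = self.retinal_lut[retinal_idx]
        for k, var in enumerate(POSTURAL_VARS):
            X[:, self.slices[var]] = self.postural_lut[posture_idx[:, k]]
        return X

    def _postural_combos(self) -> np.ndarray:
        grids = np.meshgrid(*(self.post_sel,) * 4, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def _running_max(self, combos, with_retinal: bool):
        """Chunked argmax over combo rows; returns per-neuron best + combo."""
        best = np.full(self.n_neurons, -np.inf)
        best_combo = np.zeros((self.n_neurons, combos.shape[1]), dtype=int)
        for start in range(0, len(combos), self.batch_size):
            chunk = combos[start:start + self.batch_size]
            r_idx = chunk[:, 0] if with_retinal else None
            acts = np.asarray(self.probe(
                self._assemble(r_idx, chunk[:, -4:])))
            arg = acts.argmax(axis=0)
            mx = acts[arg, np.arange(self.n_neurons)]
            better = mx > best
            best[better] = mx[better]
            best_combo[better] = chunk[arg[better]]
        return best, best_combo

    def max_without_visual(self):
        return self._running_max(self._postural_combos(), with_retinal=False)

    def _diagonal_responses(self, retinal_idx, posture_idx) -> np.ndarray:
        """Response of each neuron i to the i-th assembled input."""
        acts = np.asarray(self.probe(
            self._assemble(retinal_idx, posture_idx)))
        diag = np.arange(self.n_neurons)
        return acts[diag, diag]

    def max_with_visual(self, posture_idx):
        best = np.full(self.n_neurons, -np.inf)
        best_r = np.zeros(self.n_neurons, dtype=int)
        for r in range(self.n_retinal):
            mine = self._diagonal_responses(
                np.full(len(posture_idx), r), posture_idx)
            better = mine > best
            best[better] = mine[better]
            best_r[better] = r
        return best, best_r

    def max_full(self):
        post = self._postural_combos()
        combos = np.column_stack([
            np.repeat(np.arange(self.n_retinal), len(post)),
            np.tile(post, (self.n_retinal, 1)),
        ])
        best, best_combo = self._running_max(combos, with_retinal=True)
        return best, best_combo[:, 0], best_combo[:, 1:]

    def sweep(self, var, retinal_idx, posture_idx):
        out = np.empty((self.n_postural, self.n_neurons))
        for j in range(self.n_postural):
            combo = posture_idx.copy()
            combo[:, var] = j
            out[j] = self._diagonal_responses(retinal_idx, combo)
        return out


def _make_probe(probe, cfg: SpaceConfig | None, task: str, stride: int = 1):
    cfg = cfg or SpaceConfig()
    if hasattr(probe, "hidden_affine"):
        weight, bias = probe.hidden_affine()
        return _AffineProbe(weight, bias, cfg, task)
    if isinstance(probe, _AffineProbe) or isinstance(probe, _CallableProbe):
        return probe
    if callable(probe):
        return _CallableProbe(probe, cfg, task, stride=stride)
    raise TypeError("probe must expose hidden_affine() or be callable")


# --------------------------------------------------------------------------
# visual selection, GMI, classification
# --------------------------------------------------------------------------

def select_visual_neurons(probe, cfg: SpaceConfig | None = None,
                          task: str = "no_transformation",
                          stride: int = 1) -> pd.DataFrame:
    """Flag visually responsive neurons and record preferred inputs.

    Step 1 probes all postural combinations with the retinal (and motor)
    sections zeroed and records each neuron's maximizing posture; step 2
    probes the 49 retinal positions at that posture.  A neuron is visual
    when its peak response changes by more than 10% relative to the
    no-visual peak (absolute fallback ``> 0.01`` when the no-visual peak
    is zero).

    Returns a DataFrame with ``is_visual``, no-visual and with-visual peak
    responses, the preferred posture indices and preferred retinal index.
    """
    grid = _make_probe(probe, cfg, task, stride)
    max_no, posture_idx = grid.max_without_visual()
    max_with, retinal_idx = grid.max_with_visual(posture_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(max_with - max_no) / max_no
    is_visual = np.where(max_no > 0.0, rel > VISUAL_THRESHOLD,
                         max_with > VISUAL_ABSOLUTE_FALLBACK)
    cfg = grid.cfg
    post = cfg.postural_positions
    frame = pd.DataFrame({
        "is_visual": is_visual,
        "max_no_visual": max_no,
        "max_with_visual": max_with,
        "preferred_retinal_idx": retinal_idx,
    })
    for k, var in enumerate(POSTURAL_VARS):
        frame[f"preferred_{var}_idx"] = posture_idx[:, k]
        frame[f"preferred_{var}"] = post[posture_idx[:, k]]
    frame.index.name = "neuron"
    return frame


def compute_gmi(probe, cfg: SpaceConfig | None = None,
                task: str = "no_transformation",
                stride: int = 1) -> pd.DataFrame:
    """Four gain-modulation indices per neuron.

    From the grid combination maximizing each neuron's response, each
    postural variable is swept over its 13 values (others fixed) and
    ``GMI = (max - min) / max`` recorded.  Raises if a neuron's maximal
    response is zero (GMI undefined).
    """
    grid = _make_probe(probe, cfg, task, stride)
    act_max, retinal_idx, posture_idx = grid.max_full()
    if np.any(act_max <= 0.0):
        raise ValueError("GMI undefined: some neurons never respond")
    out = {}
    for k, var in enumerate(POSTURAL_VARS):
        sweep = grid.sweep(k, retinal_idx, posture_idx)
        mx = sweep.max(axis=0)
        mn = sweep.min(axis=0)
        out[f"gmi_{var}"] = (mx - mn) / mx
    frame = pd.DataFrame(out)
    frame.index.name = "neuron"
    return frame


def classify_gain_fields(gmi: pd.DataFrame,
                         is_visual=None,
                         threshold: float = 0.5) -> pd.Series:
    """Four-way gain-field category per visual neuron.

    A signal (eye, effector) counts as modulating when the larger of its
    horizontal/vertical GMIs reaches ``threshold``.  Non-visual neurons
    (where ``is_visual`` is False) carry no category (NaN).
    """
    eye = np.maximum(gmi["gmi_eye_x"], gmi["gmi_eye_y"]) >= threshold
    eff = np.maximum(gmi["gmi_effector_x"],
                     gmi["gmi_effector_y"]) >= threshold
    cat = np.select(
        [~eye & ~eff, eye & ~eff, ~eye & eff],
        ["pure_visual", "eye_only", "effector_only"], default="multiple")
    out = pd.Series(cat, index=gmi.index, name="category", dtype=object)
    if is_visual is not None:
        out = out.where(np.asarray(is_visual, dtype=bool), other=np.nan)
    return out


@dataclass(frozen=True)
class GainFieldDistribution:
    """Fractions of the four gain-field categories over visual neurons."""

    counts: dict
    n_visual: int
    n_total: int

    @property
    def fractions(self) -> dict:
        if self.n_visual == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: self.counts.get(c, 0) / self.n_visual for c in CATEGORIES}

    def as_dict(self) -> dict:
        out = {f"frac_{c}": v for c, v in self.fractions.items()}
        out["n_visual"] = self.n_visual
        out["n_total"] = self.n_total
        return out


@dataclass(frozen=True)
class NeuronProfile:
    """Analysis record of one hidden neuron."""

    index: int
    is_visual: bool
    preferred_posture: tuple
    gmi: tuple
    category: str | None
    rf_patch: np.ndarray | None = None


@dataclass(frozen=True)
class GainFieldAnalysis:
    """Per-neuron profiles plus the category distribution."""

    profiles: pd.DataFrame
    distribution: GainFieldDistribution
    threshold: float

    def neuron(self, i: int, model=None,
               cfg: SpaceConfig | None = None) -> NeuronProfile:
        row = self.profiles.loc[i]
        cat = row["category"]
        return NeuronProfile(
            index=i, is_visual=bool(row["is_visual"]),
            preferred_posture=tuple(row[f"preferred_{v}"]
                                    for v in POSTURAL_VARS),
            gmi=tuple(row[f"gmi_{v}"] for v in POSTURAL_VARS),
            category=None if pd.isna(cat) else cat,
            rf_patch=(receptive_field(model, i, cfg)
                      if model is not None else None))


def analyze_gain_fields(probe, cfg: SpaceConfig | None = None,
                        task: str = "no_transformation",
                        threshold: float = 0.5,
                        stride: int = 1) -> GainFieldAnalysis:
    """Full gain-field analysis: selection, GMIs, classification."""
    grid = _make_probe(probe, cfg, task, stride)
    profiles = select_visual_neurons(grid, cfg, task)
    gmi = compute_gmi(grid, cfg, task)
    profiles = profiles.join(gmi)
    cats = classify_gain_fields(gmi, profiles["is_visual"], threshold)
    profiles["category"] = cats
    counts = cats.dropna().value_counts().to_dict()
    dist = GainFieldDistribution(counts=counts,
                                 n_visual=int(profiles["is_visual"].sum()),
                                 n_total=len(profiles))
    return GainFieldAnalysis(profiles=profiles, distribution=dist,
                             threshold=threshold)


# --------------------------------------------------------------------------
# receptive fields
# --------------------------------------------------------------------------

def receptive_field(model, neuron: int,
                    cfg: SpaceConfig | None = None) -> np.ndarray:
    """Retinal slice of a neuron's incoming weights as a 17x17 patch."""
    cfg = cfg or SpaceConfig()
    weight, _ = model.hidden_affine()
    sl = input_slices(cfg, "no_transformation")["retinal"]
    n = cfg.retinal_grid_size
    return weight[neuron, sl].reshape(n, n)


def _to_gray(patch: np.ndarray) -> np.ndarray:
    """Normalize weights to [0, 1] gray; constant patches map to mid-gray."""
    lo, hi = patch.min(), patch.max()
    if hi == lo:
        return np.full_like(patch, 0.5, dtype=float)
    return (patch - lo) / (hi - lo)


def render_receptive_fields(model, neurons, path,
                            cfg: SpaceConfig | None = None,
                            n_cols: int = 10) -> None:
    """Render receptive-field patches to a grayscale PNG sheet.

    Dark pixels are inhibitory weights, light pixels excitatory; each patch
    is normalized independently (min -> black, max -> white).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    neurons = list(neurons)
    n_rows = -(-len(neurons) // n_cols)
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(n_cols, n_rows), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, i in zip(axes.ravel(), neurons):
        gray = _to_gray(receptive_field(model, i, cfg))
        ax.imshow(gray, cmap="gray", vmin=0.0, vmax=1.0, origin="lower")
        ax.set_title(str(i), fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
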