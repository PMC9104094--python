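"""Synthetic invasion scenarios with known ground truth.

Generates paired native/invaded environmental stacks and occurrence sets
for a species whose true niche is Gaussian in environmental space. The
invaded niche centre can be offset by a controlled ``shift_delta`` (the
true niche shift), and invaded-range records can spread radially from an
introduction cell over a sequence of years, so that niche unfilling
declines with time the way a real colonisation front does.

Layers are planar gradients (direction rotating per layer) scaled by a
weight, plus seeded white noise smoothed twice with a 3x3 mean filter —
a simple, reproducible form of spatial autocorrelation. Occurrence
coordinates snap to cell centres, mimicking pixel-level records; several
records may share a cell before rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import EnvLayerStack, OccurrenceSet

__all__ = [
    "NicheDefinition",
    "InvasionScenario",
    "make_env_stack",
    "true_suitability",
    "sample_occurrences",
    "make_invasion_scenario",
]


@dataclass
class NicheDefinition:
    """A Gaussian true niche: centre and breadth per environmental layer."""

    centre: np.ndarray
    breadth: np.ndarray
    label: str = "species"

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        self.breadth = np.asarray(self.breadth, dtype=float)
        if self.centre.shape != self.breadth.shape or self.centre.ndim != 1:
            raise ValueError("centre and breadth must be 1-d and the same length")
        if not (self.breadth > 0).all():
            raise ValueError("breadth must be strictly positive")

    @property
    def k(self) -> int:
        return self.centre.size


@dataclass
class InvasionScenario:
    """Bundle of paired ranges, niches and sampled occurrences."""

    native_stack: EnvLayerStack
    invaded_stack: EnvLayerStack
    native_niche: NicheDefinition
    invaded_niche: NicheDefinition
    shift_delta: np.ndarray
    introduction_cell: tuple[int, int] | None
    spread_rate: float
    years: list[int]
    seed: int
    native_occ: OccurrenceSet | None = None
    invaded_occ: OccurrenceSet | None = None

    def __post_init__(self) -> None:
        self.shift_delta = np.asarray(self.shift_delta, dtype=float)
        if not np.allclose(
            self.shift_delta, self.invaded_niche.centre - self.native_niche.centre
        ):
            raise ValueError("shift_delta must equal invaded centre - native centre")
        if self.years:
            if list(self.years) != sorted(set(self.years)):
                raise ValueError("years must be strictly increasing")


def planar_gradients(n_rows: int, n_cols: int, k_layers: int,
                     weights) -> np.ndarray:
    """Deterministic gradient component of every layer, shape (k, nr, nc).

    Layer ``j`` is a planar gradient with direction angle ``pi*j/k``,
    rescaled to span [0, 1] over the grid and multiplied by its weight —
    so the layers are linearly related through position but not collinear,
    and any grid cell's gradient-value vector is a realizable
    environmental combination (useful for anchoring true niches).
    """
    w = np.asarray(weights, dtype=float)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    xs = cc / max(n_cols - 1, 1)
    ys = rr / max(n_rows - 1, 1)
    out = []
    for j in range(k_layers):
        theta = np.pi * j / k_layers
        grad = np.cos(theta) * xs + np.sin(theta) * ys
        lo, hi = grad.min(), grad.max()
        out.append(w[j] * (grad - lo) / (hi - lo))
    return np.stack(out)


def make_env_stack(n_rows: int, n_cols: int, k_layers: int,
                   gradient_weights, noise_scale: float = 0.1,
                   correlation_pairs=None, seed: int = 0,
                   cell_size: float = 1.0, origin=(0.0, 0.0),
                   layer_names=None) -> EnvLayerStack:
    """Build a k-layer stack of planar gradients plus smoothed noise.

    Layer ``j`` is a planar gradient with direction angle ``pi*j/k`` (so
    layers are not collinear by construction) scaled by
    ``gradient_weights[j]``, plus Gaussian noise of sd ``noise_scale``
    smoothed by two passes of a 3x3 mean filter. ``correlation_pairs``
    forces listed (i, j) layer pairs to |Pearson r| >= 0.9 by rebuilding
    layer j as layer i plus small noise.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8x8")
    if k_layers < 2:
        raise ValueError("need at least two layers")
    w = np.asarray(gradient_weights, dtype=float)
    if w.shape != (k_layers,):
        raise ValueError("gradient_weights length must equal k_layers")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")

    rng = np.random.default_rng(seed)
    grads = planar_gradients(n_rows, n_cols, k_layers, w)
    layers = []
    for j in range(k_layers):
        noise = rng.standard_normal((n_rows, n_cols)) * noise_scale
        if noise_scale > 0:
            noise = ndimage.uniform_filter(
                ndimage.uniform_filter(noise, size=3, mode="nearest"),
                size=3, mode="nearest")
        layers.append(grads[j] + noise)
    values = np.stack(layers)

    for (i, j) in (correlation_pairs or []):
        sd = values[i].std()
        jitter = rng.standard_normal((n_rows, n_cols)) * 0.2 * sd
        values[j] = values[i] + jitter

    names = (list(layer_names) if layer_names is not None
             else [f"env{j}" for j in range(k_layers)])
    return EnvLayerStack(values, names, cell_size, origin)


def true_suitability(stack: EnvLayerStack, niche: NicheDefinition) -> np.ndarray:
    """Ground-truth suitability: product of per-layer Gaussians, in [0, 1].

    Equals 1 exactly at the niche centre; invalid cells get 0.
    """
    if stack.k != niche.k:
        raise ValueError("stack layer count does not match niche dimensionality")
    c = niche.centre[:, None, None]
    b = niche.breadth[:, None, None]
    suit = np.exp(-((stack.values - c) ** 2) / (2 * b ** 2)).prod(axis=0)
    suit[~stack.valid_mask] = 0.0
    return suit


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n draws to weighted bins."""
    q = n * weights / weights.sum()
    counts = np.floor(q).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(q - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def sample_occurrences(suitability: np.ndarray, n: int, seed: int = 0,
                       stack: EnvLayerStack | None = None,
                       introduction_cell: tuple[int, int] | None = None,
                       spread_rate: float | None = None,
                       years: list[int] | None = None,
                       population: str = "native") -> OccurrenceSet:
    """Sample ``n`` presence records with probability proportional to suitability.

    With an introduction cell and a spread rate, a cell is eligible in
    year ``t`` only while its grid distance (Euclidean, in cells) from the
    introduction does not exceed ``spread_rate * (t - years[0])``; record
    counts per year grow linearly with time since introduction, emulating
    an expanding citizen-science record stream. Coordinates are cell
    centres.
    """
    suit = np.asarray(suitability, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    if suit.sum() <= 0:
        raise ValueError("suitability must have positive mass")
    rng = np.random.default_rng(seed)
    nr, nc = suit.shape
    rows, cols = np.unravel_index(np.arange(nr * nc), (nr, nc))

    def draw(p: np.ndarray, size: int) -> np.ndarray:
        return rng.choice(nr * nc, size=size, p=p / p.sum())

    if introduction_cell is None or years is None:
        idx = draw(suit.ravel(), n)
        yrs = pd.array([years[0]] * n if years else [pd.NA] * n, dtype="Int64")
    else:
        r0, c0 = introduction_cell
        dist = np.hypot(rows.reshape(nr, nc) - r0, cols.reshape(nr, nc) - c0)
        rate = 0.0 if spread_rate is None else float(spread_rate)
        weights = np.arange(1, len(years) + 1, dtype=float)
        counts = _apportion(n, weights)
        idx_parts, yr_parts = [], []
        for t, n_t in zip(years, counts):
            eligible = dist <= rate * (t - years[0])
            p = (suit * eligible).ravel()
            if p.sum() <= 0:
                raise ValueError(f"no eligible cell with positive suitability in year {t}")
            if n_t:
                idx_parts.append(draw(p, int(n_t)))
                yr_parts.extend([t] * int(n_t))
        idx = np.concatenate(idx_parts)
        yrs = pd.array(yr_parts, dtype="Int64")

    r, c = rows[idx], cols[idx]
    if stack is not None:
        x, y = stack.cell_center(r, c)
    else:
        x, y = c + 0.5, -(r + 0.5)
    return OccurrenceSet(pd.DataFrame(
        {"x": x, "y": y, "year": yrs, "population": population}))


def make_invasion_scenario(config: dict) -> InvasionScenario:
    """Assemble a full two-range scenario from a flat config mapping.

    Recognised keys (defaults in parentheses): ``n_rows`` (48), ``n_cols``
    (48), ``k_layers`` (4), ``gradient_weights`` (ones), ``noise_scale``
    (0.1), ``correlation_pairs`` (none), ``cell_size`` (5.0 km),
    ``native_centre``, ``native_breadth``, ``shift_delta`` (zeros),
    ``native_centre_cell`` / ``invaded_centre_cell`` (anchor the niche
    centres to the gradient values of those grid cells, guaranteeing a
    realizable combination; they override ``native_centre`` /
    ``shift_delta``), ``invaded_breadth`` (= native), ``n_native`` (400),
    ``n_invaded``
    (800), ``introduction_cell`` (none), ``spread_rate`` (0), ``years``
    ([]), ``seed`` (0), ``invaded_stack_offset`` (0 per layer: constant
    added to every invaded-range layer, to displace the available
    envelope).
    """
    cfg = dict(config)
    nr = int(cfg.get("n_rows", 48)); nc = int(cfg.get("n_cols", 48))
    k = int(cfg.get("k_layers", 4))
    w = np.asarray(cfg.get("gradient_weights", np.ones(k)), dtype=float)
    noise = float(cfg.get("noise_scale", 0.1))
    pairs = cfg.get("correlation_pairs")
    cell = float(cfg.get("cell_size", 5.0))
    seed = int(cfg.get("seed", 0))

    grads = planar_gradients(nr, nc, k, w)
    if "native_centre_cell" in cfg:
        r0, c0 = cfg["native_centre_cell"]
        native_centre = grads[:, int(r0), int(c0)].copy()
    else:
        native_centre = np.asarray(cfg.get("native_centre", np.full(k, 0.5)),
                                   float)
    native_breadth = np.asarray(cfg.get("native_breadth", np.full(k, 0.25)), float)
    if "invaded_centre_cell" in cfg:
        r1, c1 = cfg["invaded_centre_cell"]
        delta = grads[:, int(r1), int(c1)] - native_centre
    else:
        delta = np.asarray(cfg.get("shift_delta", np.zeros(k)), float)
    invaded_breadth = np.asarray(cfg.get("invaded_breadth", native_breadth), float)
    if delta.shape != native_centre.shape:
        raise ValueError("shift_delta length must match niche dimensionality")

    native_stack = make_env_stack(nr, nc, k, w, noise, pairs, seed=seed,
                                  cell_size=cell)
    invaded_stack = make_env_stack(nr, nc, k, w, noise, pairs, seed=seed + 1,
                                   cell_size=cell, origin=(nc * cell * 2, 0.0))
    offset = np.asarray(cfg.get("invaded_stack_offset", np.zeros(k)), float)
    invaded_stack.values += offset[:, None, None]

    native_niche = NicheDefinition(native_centre, native_breadth, "native")
    invaded_niche = NicheDefinition(native_centre + delta, invaded_breadth, "invaded")

    years = [int(y) for y in cfg.get("years", [])]
    intro = cfg.get("introduction_cell")
    intro = tuple(int(v) for v in intro) if intro is not None else None
    rate = float(cfg.get("spread_rate", 0.0))

    native_occ = sample_occurrences(
        true_suitability(native_stack, native_niche),
        int(cfg.get("n_native", 400)), seed=seed + 2, stack=native_stack,
        population="native")
    invaded_occ = sample_occurrences(
        true_suitability(invaded_stack, invaded_niche),
        int(cfg.get("n_invaded", 800)), seed=seed + 3, stack=invaded_stack,
        introduction_cell=intro, spread_rate=rate,
        years=years or None, population="P1")

    return InvasionScenario(
        native_stack, invaded_stack, native_niche, invaded_niche, delta,
        intro, rate, years, seed, native_occ, invaded_occ)
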