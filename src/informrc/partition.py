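"""Dataset assembly: splits, merged test series, normalisation, look-ahead.

The cycle-based partition mirrors the reaching protocol: cycles 1–6 of
the trials in the trained directions (A, C, E) form the training data,
cycles 7–8 the validation data, and cycles 9–10 the *Basic* test set.
All cycles of the untrained directions (B, D) form the *Morphing* test
set, and the four transition trials the *Natural Transitions* test set.
Basic and Morphing items are merged in a seeded random order into one
long series with a randomly chosen member prepended as initialisation
prefix, which is excluded from evaluation.  Every channel is min-max
normalised with statistics from the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _scipy_detrend

from .arm import Dataset, TRAIN_DIRECTIONS, MORPH_DIRECTIONS
from .signals import SignalBundle, GROUPS, concatenate

__all__ = [
    "SplitItem",
    "DatasetSplits",
    "build_splits",
    "build_train_series",
    "assemble_test_series",
    "Normalizer",
    "fit_normalizer",
    "build_lookahead_inputs",
    "segment_cycles",
    "remove_drift",
    "ExperimentSeries",
    "prepare_series",
]

TRAIN_CYCLES = (1, 6)
VALIDATION_CYCLES = (7, 8)
BASIC_CYCLES = (9, 10)


@dataclass
class SplitItem:
    condition: str
    cycles: tuple[int, int]        # 1-based inclusive cycle range
    bundle: SignalBundle


@dataclass
class DatasetSplits:
    train: list[SplitItem]
    validation: list[SplitItem]
    basic: list[SplitItem]
    morphing: list[SplitItem]
    natural: list[SignalBundle]
    seed: int = 0

    def manifest(self) -> list[dict]:
        rows = []
        for name in ("train", "validation", "basic", "morphing"):
            for it in getattr(self, name):
                rows.append({"split": name, "condition": it.condition,
                             "cycles": list(it.cycles)})
        for b in self.natural:
            rows.append({"split": "natural",
                         "condition": b.meta.get("condition"), "cycles": "all"})
        return rows


def build_splits(dataset: Dataset, seed: int = 0) -> DatasetSplits:
    """Partition a dataset by direction and cycle index.

    Raises if any main trial has fewer than 10 segmented cycles.  Cycle
    disjointness between splits holds by construction (1–6 / 7–8 / 9–10
    for trained directions; untrained directions appear only in the
    morphing split).
    """
    train, val, basic, morph = [], [], [], []
    for label, b in dataset.trials.items():
        if b.n_cycles < 10:
            raise ValueError(f"trial {label} has only {b.n_cycles} cycles")
        direction = b.meta["direction"]
        if direction in TRAIN_DIRECTIONS:
            train.append(SplitItem(label, TRAIN_CYCLES, b.cycles(*TRAIN_CYCLES)))
            val.append(SplitItem(label, VALIDATION_CYCLES, b.cycles(*VALIDATION_CYCLES)))
            basic.append(SplitItem(label, BASIC_CYCLES, b.cycles(*BASIC_CYCLES)))
        elif direction in MORPH_DIRECTIONS:
            morph.append(SplitItem(label, (1, b.n_cycles), b.cycles(1, b.n_cycles)))
        else:  # pragma: no cover - directions are a fixed five-element set
            raise ValueError(f"unassignable direction {direction!r}")
    return DatasetSplits(train=train, validation=val, basic=basic,
                         morphing=morph, natural=list(dataset.natural), seed=seed)


def build_train_series(splits: DatasetSplits, seed: int | None = None) -> SignalBundle:
    """Concatenate the training items in a seeded random order."""
    rng = np.random.default_rng(splits.seed if seed is None else seed)
    order = rng.permutation(len(splits.train))
    return concatenate([splits.train[i].bundle for i in order])


def assemble_test_series(items: list[SplitItem], seed: int,
                         prefix_pool: list[SignalBundle] | None = None
                         ) -> tuple[SignalBundle, np.ndarray]:
    """Merge split items in random order and prepend an initialisation prefix.

    A seeded random member (of ``prefix_pool``, default the items
    themselves) is prepended; the returned boolean mask is False over the
    prefix so the network's transient is excluded from evaluation.
    """
    if not items:
        raise ValueError("empty split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    pool = prefix_pool if prefix_pool is not None else [it.bundle for it in items]
    prefix = pool[int(rng.integers(len(pool)))]
    series = concatenate([prefix] + [items[i].bundle for i in order])
    mask = np.arange(series.n_samples) >= prefix.n_samples
    return series, mask


class Normalizer:
    """Per-channel min-max normalisation fitted on the training series.

    Channels whose training range is zero (e.g. the constant tabletop z)
    are flagged degenerate: they map to 0 under ``transform`` and are
    restored exactly by ``inverse``.  Test values may legitimately fall
    outside [0, 1].
    """

    def __init__(self) -> None:
        self.mins: dict[str, np.ndarray] = {}
        self.maxs: dict[str, np.ndarray] = {}

    def fit(self, train: SignalBundle) -> "Normalizer":
        for g in GROUPS:
            arr = train.group(g)
            self.mins[g] = arr.min(axis=1)
            self.maxs[g] = arr.max(axis=1)
        return self

    def degenerate(self, group: str) -> np.ndarray:
        return self.maxs[group] == self.mins[group]

    def _scale(self, group: str) -> np.ndarray:
        span = self.maxs[group] - self.mins[group]
        return np.where(span == 0, 1.0, span)

    def transform_group(self, group: str, arr: np.ndarray) -> np.ndarray:
        return (arr - self.mins[group][:, None]) / self._scale(group)[:, None]

    def inverse_group(self, group: str, arr: np.ndarray) -> np.ndarray:
        return arr * self._scale(group)[:, None] + self.mins[group][:, None]

    def transform(self, bundle: SignalBundle) -> SignalBundle:
        return SignalBundle(
            self.transform_group("goal", bundle.goal),
            self.transform_group("efference", bundle.efference),
            self.transform_group("afference", bundle.afference),
            fs=bundle.fs, cycle_bounds=bundle.cycle_bounds, meta=bundle.meta)

    def inverse(self, bundle: SignalBundle) -> SignalBundle:
        return SignalBundle(
            self.inverse_group("goal", bundle.goal),
            self.inverse_group("efference", bundle.efference),
            self.inverse_group("afference", bundle.afference),
            fs=bundle.fs, cycle_bounds=bundle.cycle_bounds, meta=bundle.meta)


def fit_normalizer(train: SignalBundle) -> Normalizer:
    return Normalizer().fit(train)


def build_lookahead_inputs(goal: np.ndarray, horizon: float = 0.3,
                           n_taps: int = 7, fs: float = 120.0,
                           wrap: bool = False) -> np.ndarray:
    """Stack the goal at future offsets into a (3 * n_taps) x T input.

    Tap ``k`` holds the goal ``k * H / (n_taps - 1)`` samples ahead, with
    the current sample always included; the series end pads by holding
    the last value (or wraps when ``wrap=True``, for purely cyclic data).
    """
    goal = np.atleast_2d(np.asarray(goal, dtype=float))
    T = goal.shape[1]
    if T == 0:
        raise ValueError("empty goal series")
    if n_taps < 1:
        raise ValueError("n_taps must be >= 1")
    H = int(round(horizon * fs))
    if n_taps > 1 and H < n_taps - 1:
        raise ValueError("look-ahead horizon shorter than the tap count")
    offsets = (np.round(np.linspace(0, H, n_taps)).astype(int)
               if n_taps > 1 else np.array([0]))
    blocks = []
    idx = np.arange(T)
    for off in offsets:
        j = idx + off
        j = j % T if wrap else np.minimum(j, T - 1)
        blocks.append(goal[:, j])
    return np.vstack(blocks)


def segment_cycles(goal_xy: np.ndarray, fs: float, min_period: float = 0.5,
                   hysteresis: float = 0.05) -> np.ndarray:
    """Cycle boundaries for imported data: returns to the central target.

    Detects samples where radial distance from the origin (the central
    target after drift removal) falls below ``hysteresis`` of its peak
    after having exceeded half of it, enforcing a minimum period.
    Synthetic bundles carry exact boundaries, so this is only needed for
    recorded kinematics.
    """
    r = np.hypot(*np.atleast_2d(goal_xy)[:2])
    peak = np.max(r)
    low, high = hysteresis * peak, 0.5 * peak
    bounds, armed, last = [0], False, 0
    min_gap = int(min_period * fs)
    for t in range(len(r)):
        if r[t] > high:
            armed = True
        elif armed and r[t] < low and t - last >= min_gap:
            bounds.append(t)
            last, armed = t, False
    bounds.append(len(r))
    return np.asarray(sorted(set(bounds)), dtype=int)


def remove_drift(signal: np.ndarray) -> np.ndarray:
    """Linear detrend for imported kinematics (a no-op on synthetic data)."""
    return _scipy_detrend(np.asarray(signal, dtype=float), axis=-1, type="linear")


@dataclass
class ExperimentSeries:
    """Normalised, merged series ready for training and closed-loop testing.

    ``tests`` maps split name to a list of ``(series, eval_mask)`` pairs
    (one entry for basic/morphing/validation, four for natural); all
    series are in normalised units, with the normaliser retained so
    metrics can be computed in original units.
    """

    train: SignalBundle
    tests: dict[str, list[tuple[SignalBundle, np.ndarray]]]
    normalizer: Normalizer
    splits: DatasetSplits
    n_taps: int
    fs: float

    def goal_window(self, bundle: SignalBundle) -> np.ndarray:
        return build_lookahead_inputs(bundle.goal, n_taps=self.n_taps, fs=self.fs)


def prepare_series(dataset: Dataset, seed: int = 0, n_taps: int = 7) -> ExperimentSeries:
    """Build splits, fit the normaliser and assemble every merged series.

    The assembly seed controls merge orders and prefix choices only; it
    is independent of network instance seeds.
    """
    splits = build_splits(dataset, seed)
    train_raw = build_train_series(splits, seed)
    norm = fit_normalizer(train_raw)
    ss = np.random.SeedSequence([seed, 2])
    sub = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(3 + len(splits.natural))]

    def norm_pair(pair):
        series, mask = pair
        return norm.transform(series), mask

    tests: dict[str, list] = {
        "validation": [norm_pair(assemble_test_series(splits.validation, sub[0]))],
        "basic": [norm_pair(assemble_test_series(splits.basic, sub[1]))],
        "morphing": [norm_pair(assemble_test_series(splits.morphing, sub[2]))],
    }
    # one of the 20 standard conditions (full trial) prepended as initialisation
    standard_pool = list(dataset.trials.values())
    nat = []
    for i, b in enumerate(splits.natural):
        rng = np.random.default_rng(sub[3 + i])
        prefix = standard_pool[int(rng.integers(len(standard_pool)))]
        series = concatenate([prefix, b])
        mask = np.arange(series.n_samples) >= prefix.n_samples
        nat.append(norm_pair((series, mask)))
    tests["natural"] = nat
    return ExperimentSeries(train=norm.transform(train_raw), tests=tests,
                            normalizer=norm, splits=splits, n_taps=n_taps,
                            fs=dataset.fs)
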