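"""Aligned multichannel sensorimotor time series.

A :class:`SignalBundle` is the universal currency between the generator,
the partitioning code and the networks: goal kinematics, efferent
(muscle-activation) channels and afferent (muscle length and velocity)
channels sampled on a common clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SignalBundle", "GROUPS"]

GROUPS = ("goal", "efference", "afference")


@dataclass
class SignalBundle:
    """Goal / efference / afference channels over T samples at rate ``fs``.

    ``goal`` is ``3 x T`` (endpoint x, y, z in metres, z constant on the
    tabletop), ``efference`` is ``n_muscles x T`` activations in [0, 1],
    ``afference`` is ``2*n_muscles x T`` (all lengths, then all velocities).
    ``cycle_bounds`` holds the start index of each movement cycle plus the
    final end index, so cycle ``i`` spans ``[cycle_bounds[i], cycle_bounds[i+1])``.
    """

    goal: np.ndarray
    efference: np.ndarray
    afference: np.ndarray
    fs: float = 120.0
    cycle_bounds: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.goal = np.atleast_2d(np.asarray(self.goal, dtype=float))
        self.efference = np.atleast_2d(np.asarray(self.efference, dtype=float))
        self.afference = np.atleast_2d(np.asarray(self.afference, dtype=float))
        self.cycle_bounds = np.asarray(self.cycle_bounds, dtype=int)
        T = self.goal.shape[1]
        if self.efference.shape[1] != T or self.afference.shape[1] != T:
            raise ValueError("goal/efference/afference lengths differ")

    @property
    def n_samples(self) -> int:
        return self.goal.shape[1]

    @property
    def n_cycles(self) -> int:
        return max(len(self.cycle_bounds) - 1, 0)

    def group(self, name: str) -> np.ndarray:
        if name not in GROUPS:
            raise KeyError(name)
        return getattr(self, name)

    def stacked(self) -> np.ndarray:
        """All 27 channels as one matrix, goal, efference then afference."""
        return np.vstack([self.goal, self.efference, self.afference])

    def channel_labels(self) -> list[str]:
        n_m = self.efference.shape[0]
        labels = ["goal_x", "goal_y", "goal_z"][: self.goal.shape[0]]
        labels += [f"eff_{i + 1}" for i in range(n_m)]
        labels += [f"len_{i + 1}" for i in range(self.afference.shape[0] // 2)]
        labels += [f"vel_{i + 1}" for i in range(self.afference.shape[0] // 2)]
        return labels

    def slice(self, start: int, stop: int) -> "SignalBundle":
        """Sample-range view with cycle bounds re-indexed into the slice."""
        cb = self.cycle_bounds
        cb = cb[(cb >= start) & (cb <= stop)] - start
        return SignalBundle(self.goal[:, start:stop],
                            self.efference[:, start:stop],
                            self.afference[:, start:stop],
                            fs=self.fs, cycle_bounds=cb, meta=dict(self.meta))

    def cycles(self, first: int, last: int) -> "SignalBundle":
        """Sub-bundle holding cycles ``first..last`` (1-based, inclusive)."""
        if self.n_cycles < last:
            raise ValueError(f"bundle has {self.n_cycles} cycles, need {last}")
        return self.slice(int(self.cycle_bounds[first - 1]),
                          int(self.cycle_bounds[last]))

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stacked().T, columns=self.channel_labels())
        df.insert(0, "t", np.arange(self.n_samples) / self.fs)
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            side = {"fs": self.fs,
                    "cycle_bounds": self.cycle_bounds.tolist(),
                    "meta": _jsonable(self.meta)}
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "SignalBundle":
        df = pd.read_csv(path)
        goal = df[[c for c in df.columns if c.startswith("goal_")]].to_numpy().T
        eff = df[[c for c in df.columns if c.startswith("eff_")]].to_numpy().T
        lens = df[[c for c in df.columns if c.startswith("len_")]].to_numpy().T
        vels = df[[c for c in df.columns if c.startswith("vel_")]].to_numpy().T
        fs, cb, meta = 120.0, np.array([], dtype=int), {}
        try:
            with open(str(path) + ".json") as fh:
                side = json.load(fh)
            fs = side.get("fs", fs)
            cb = np.asarray(side.get("cycle_bounds", []), dtype=int)
            meta = side.get("meta", {})
        except FileNotFoundError:
            pass
        return cls(goal, eff, np.vstack([lens, vels]), fs=fs,
                   cycle_bounds=cb, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def concatenate(bundles: list[SignalBundle]) -> SignalBundle:
    """Join bundles end to end, merging cycle bounds."""
    if not bundles:
        raise ValueError("nothing to concatenate")
    fs = bundles[0].fs
    offs, cb = 0, []
    for b in bundles:
        if b.fs != fs:
            raise ValueError("sampling rates differ")
        bounds = b.cycle_bounds if len(b.cycle_bounds) else np.array([0, b.n_samples])
        for v in bounds[:-1]:
            cb.append(offs + int(v))
        offs += b.n_samples
    cb.append(offs)
    return SignalBundle(
        np.hstack([b.goal for b in bundles]),
        np.hstack([b.efference for b in bundles]),
        np.hstack([b.afference for b in bundles]),
        fs=fs, cycle_bounds=np.array(sorted(set(cb)), dtype=int),
        meta={"segments": [b.meta.get("condition") for b in bundles]})
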