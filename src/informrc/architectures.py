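"""The five sensorimotor network architectures and their execution.

``InFoRM`` is a single reservoir that simultaneously emits the movement
goal (recognition), the muscle activations (inverse function) and the
predicted proprioceptive feedback (forward function).  The four control
architectures implement the classic hierarchical scheme with separate
inverse and forward reservoirs; the ``+A`` / ``+G`` / ``+AG`` variants
grant the subnetworks additional afferent input, goal input, or both, so
that ``Control+AG`` consumes exactly the same external information as
``InFoRM`` and any remaining performance gap is architectural.

During training every feedback signal is overwritten by its target
(teacher forcing); during testing only the goal is external — the current
goal plus a look-ahead window drives the loop while efference and
afference circulate as output feedback, the forward network receiving a
synchronous efference copy from the inverse network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reservoir import ReservoirConfig, ReservoirParams, init_reservoir
from .rls import TrainConfig, TrainLogEntry, train_readout_forced
from .signals import SignalBundle, GROUPS

__all__ = [
    "ARCHITECTURE_NAMES",
    "NetworkSpec",
    "ArchitectureSpec",
    "TrainedArchitecture",
    "build_architecture",
    "init_architecture",
    "network_seed",
    "train_teacher_forced",
    "run_test_closed_loop",
    "external_information",
]

ARCHITECTURE_NAMES = ("InFoRM", "Control", "Control+A", "Control+G", "Control+AG")

DEFAULT_DIMS = {"goal": 3, "efference": 8, "afference": 16}


@dataclass(frozen=True)
class NetworkSpec:
    """One reservoir: what it reads, what it emits, and its hyperparameters.

    ``inputs`` are signal sources routed through the input matrix
    (current-sample goal window / synchronous efference copy /
    previous-sample afference); ``outputs`` are the groups it emits, which
    are also its output-feedback channels.
    """

    name: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    config: ReservoirConfig


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    networks: tuple[NetworkSpec, ...]
    dims: dict = field(default_factory=lambda: dict(DEFAULT_DIMS))
    n_taps: int = 7

    def input_dim(self, net: NetworkSpec) -> int:
        tot = 0
        for src in net.inputs:
            tot += (self.dims["goal"] * self.n_taps if src == "goal_window"
                    else self.dims[src])
        return tot

    def output_dim(self, net: NetworkSpec) -> int:
        return sum(self.dims[g] for g in net.outputs)

    @property
    def n_output_channels(self) -> int:
        return sum(self.output_dim(n) for n in self.networks)

    def total_neurons(self) -> int:
        return sum(n.config.n_neurons for n in self.networks)

    def validate(self) -> None:
        produced = [g for n in self.networks for g in n.outputs]
        if len(produced) != len(set(produced)):
            raise ValueError("a signal group is produced by two networks")
        for n in self.networks:
            for src in n.inputs:
                if src == "goal_window":
                    continue  # always externally available
                if src not in produced:
                    raise ValueError(f"{n.name} consumes {src}, produced nowhere")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {"name": self.name, "dims": dict(self.dims), "n_taps": self.n_taps,
                "networks": [{"name": n.name, "inputs": list(n.inputs),
                              "outputs": list(n.outputs),
                              "config": asdict(n.config)} for n in self.networks]}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        nets = tuple(NetworkSpec(n["name"], tuple(n["inputs"]), tuple(n["outputs"]),
                                 ReservoirConfig(**n["config"]))
                     for n in d["networks"])
        return cls(d["name"], nets, dims=dict(d["dims"]), n_taps=d["n_taps"])


def build_architecture(name: str,
                       dims: dict | None = None,
                       configs: dict[str, ReservoirConfig] | ReservoirConfig | None = None,
                       n_taps: int = 7) -> ArchitectureSpec:
    """Construct one of the five named architectures.

    ``configs`` may be a single :class:`ReservoirConfig` applied to every
    subnetwork or a mapping from subnetwork name (``"inform"``,
    ``"inverse"``, ``"forward"``) to a config.
    """
    dims = dict(DEFAULT_DIMS) if dims is None else dict(dims)
    if configs is None:
        configs = ReservoirConfig()

    def cfg(net_name: str) -> ReservoirConfig:
        if isinstance(configs, dict):
            return configs[net_name]
        return configs

    if name == "InFoRM":
        nets = (NetworkSpec("inform", ("goal_window",),
                            ("goal", "efference", "afference"), cfg("inform")),)
    elif name in ("Control", "Control+A", "Control+G", "Control+AG"):
        inv_in = ["goal_window"]
        fwd_in = []
        if name in ("Control+A", "Control+AG"):
            inv_in.append("afference")
        if name in ("Control+G", "Control+AG"):
            fwd_in.append("goal_window")
        fwd_in.append("efference")
        nets = (NetworkSpec("inverse", tuple(inv_in), ("efference",), cfg("inverse")),
                NetworkSpec("forward", tuple(fwd_in), ("afference",), cfg("forward")))
    else:
        raise ValueError(f"unknown architecture name {name!r}; "
                         f"expected one of {ARCHITECTURE_NAMES}")
    spec = ArchitectureSpec(name, nets, dims=dims, n_taps=n_taps)
    spec.validate()
    return spec


def external_information(spec: ArchitectureSpec) -> dict[str, frozenset]:
    """Signal groups visible to each subnetwork (inputs plus feedback).

    The information-parity audit between ``InFoRM`` and ``Control+AG``:
    in both, every subnetwork sees goal, efference and afference, so any
    performance difference is architectural; in the plain ``Control``
    neither subnetwork sees all three.
    """
    vis = {}
    for net in spec.networks:
        groups = {"goal" if s == "goal_window" else s for s in net.inputs}
        groups.update(net.outputs)
        vis[net.name] = frozenset(groups)
    return vis


def has_full_information(spec: ArchitectureSpec) -> bool:
    """True when every subnetwork sees all three signal groups."""
    full = frozenset(GROUPS)
    return all(v == full for v in external_information(spec).values())


def network_seed(instance_seed: int, network_index: int) -> int:
    """Architecture-independent derived seed for subnetwork ``network_index``.

    The same instance seed yields the same per-slot reservoir seeds for
    every architecture, so matched-seed comparisons are fair.
    """
    return int(np.random.SeedSequence([instance_seed, network_index])
               .generate_state(1)[0] % (2 ** 31))


def init_architecture(spec: ArchitectureSpec,
                      instance_seed: int | None = None) -> dict[str, ReservoirParams]:
    """Draw the fixed matrices of every subnetwork.

    When ``instance_seed`` is given, each subnetwork's seed is derived
    from it by slot index (architecture-independently); otherwise the
    seeds in the configs are used as-is.
    """
    params = {}
    for i, net in enumerate(spec.networks):
        cfg = net.config
        if instance_seed is not None:
            cfg = cfg.replace(seed=network_seed(instance_seed, i))
        params[net.name] = init_reservoir(cfg, spec.input_dim(net),
                                          spec.output_dim(net))
    return params


@dataclass
class TrainedArchitecture:
    spec: ArchitectureSpec
    params: dict[str, ReservoirParams]
    readouts: dict[str, np.ndarray]
    train_log: dict[str, list[TrainLogEntry]] = field(default_factory=dict)


def _prev(M: np.ndarray) -> np.ndarray:
    """Shift columns one sample into the past, clamping the first sample."""
    return np.hstack([M[:, :1], M[:, :-1]])


def _targets_of(bundle: SignalBundle, groups: tuple[str, ...]) -> np.ndarray:
    return np.vstack([bundle.group(g) for g in groups])


def assemble_training_streams(spec: ArchitectureSpec, bundle: SignalBundle,
                              goal_window: np.ndarray) -> dict[str, dict]:
    """Per-network forced input/feedback/target matrices for one pass.

    Feedback matrices are already time-aligned (column ``t`` holds the
    target of ``t-1``); rows flagged in ``noise_rows`` are target-derived
    and receive training noise, the recorded goal window does not.
    """
    streams: dict[str, dict] = {}
    for net in spec.networks:
        rows, mask = [], []
        for src in net.inputs:
            if src == "goal_window":
                rows.append(goal_window)
                mask.append(np.zeros(goal_window.shape[0], dtype=bool))
            elif src == "efference":
                rows.append(bundle.efference)  # synchronous efference copy
                mask.append(np.ones(bundle.efference.shape[0], dtype=bool))
            elif src == "afference":
                rows.append(_prev(bundle.afference))
                mask.append(np.ones(bundle.afference.shape[0], dtype=bool))
            else:
                raise ValueError(f"unknown input source {src!r}")
        tgt = _targets_of(bundle, net.outputs)
        streams[net.name] = dict(
            inputs=np.vstack(rows),
            noise_rows=np.concatenate(mask),
            feedback=_prev(tgt),
            targets=tgt,
        )
    return streams


def train_teacher_forced(spec: ArchitectureSpec, bundle: SignalBundle,
                         cfg: TrainConfig,
                         params: dict[str, ReservoirParams] | None = None,
                         goal_window: np.ndarray | None = None) -> TrainedArchitecture:
    """Train every subnetwork's readout under full target overwriting.

    All output-feedback slots (and all target-derived input slots) carry
    noisy targets; each subnetwork is therefore trained independently of
    the others' readouts, mirroring the simultaneous training of the
    inverse and forward subnetworks.
    """
    from .partition import build_lookahead_inputs

    if params is None:
        params = init_architecture(spec)
    if goal_window is None:
        goal_window = build_lookahead_inputs(bundle.goal, fs=bundle.fs,
                                             n_taps=spec.n_taps)
    streams = assemble_training_streams(spec, bundle, goal_window)
    rng = np.random.default_rng(cfg.seed)
    readouts, logs = {}, {}
    for net in spec.networks:
        s = streams[net.name]
        W_out, log = train_readout_forced(params[net.name], s["inputs"],
                                          s["noise_rows"], s["feedback"],
                                          s["targets"], cfg, rng)
        readouts[net.name] = W_out
        logs[net.name] = log
    return TrainedArchitecture(spec=spec, params=params, readouts=readouts,
                               train_log=logs)


def run_test_closed_loop(trained: TrainedArchitecture,
                         goal: np.ndarray,
                         goal_window: np.ndarray,
                         init_prefix_len: int = 0) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Closed-loop execution: goal external, efference/afference fed back.

    Per sample, networks run in declaration order (inverse before
    forward), so the forward network consumes the inverse network's
    efference output of the same sample.  Afference routed to the inverse
    network (``Control+A``/``+AG``) is the forward network's previous
    output.  For ``InFoRM`` the goal feedback slot is overwritten with
    the external goal; its emitted goal output is still recorded (the
    recognition readout).

    Returns ``(outputs, eval_mask)`` where ``outputs`` maps each produced
    group to its predicted series and ``eval_mask`` flags the samples
    after the initialisation prefix.
    """
    spec = trained.spec
    goal = np.atleast_2d(goal)
    T = goal.shape[1]
    if goal_window.shape[1] != T:
        raise ValueError("goal and goal_window lengths differ")
    for net in spec.networks:
        if net.name not in trained.readouts:
            raise KeyError(f"missing trained readout for network {net.name!r}")

    lam = {n.name: n.config.leak_rate for n in spec.networks}
    x = {n.name: np.zeros(trained.params[n.name].n_neurons) for n in spec.networks}
    # previous-sample value of each produced group (efference/afference
    # start at zero; the goal slot is externally overwritten)
    prev = {g: np.zeros(spec.dims[g]) for n in spec.networks for g in n.outputs}
    rec = {g: np.empty((spec.dims[g], T)) for g in prev}

    for t in range(T):
        cur: dict[str, np.ndarray] = {}
        goal_prev = goal[:, t - 1] if t > 0 else goal[:, 0]
        for net in spec.networks:
            p = trained.params[net.name]
            u_parts = []
            for src in net.inputs:
                if src == "goal_window":
                    u_parts.append(goal_window[:, t])
                elif src == "efference":
                    u_parts.append(cur.get("efference", prev["efference"]))
                elif src == "afference":
                    u_parts.append(prev["afference"])
            u = np.concatenate(u_parts) if u_parts else np.empty(0)
            fb = np.concatenate([goal_prev if g == "goal" else prev[g]
                                 for g in net.outputs])
            xi = x[net.name]
            pre = p.W @ xi + p.W_in @ u + p.W_fb @ fb + p.bias
            xi = (1.0 - lam[net.name]) * xi + lam[net.name] * np.tanh(pre)
            x[net.name] = xi
            y = trained.readouts[net.name] @ xi
            off = 0
            for g in net.outputs:
                d = spec.dims[g]
                cur[g] = y[off:off + d]
                rec[g][:, t] = cur[g]
                off += d
        prev.update(cur)

    eval_mask = np.arange(T) >= init_prefix_len
    return rec, eval_mask
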