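"""Synthetic planar-arm reaching data generator.

Emulates the signal structure of tabletop cyclic reaching: a two-link
planar arm (shoulder + elbow, no gravity in the horizontal plane) with a
redundant set of constant-moment-arm muscles performs minimum-jerk
back-and-forth reaches between a central target and ten peripheral
targets (5 directions x 2 amplitudes), paced at 1.0 or 0.75 Hz.  Joint
torques from inverse dynamics are resolved into muscle activations by
static optimisation (minimum sum of squared activations under torque
equality and [0, 1] bounds), and afferent signals are the muscle lengths
and velocities of the selected muscles.  Smooth endpoint jitter emulates
human cycle-to-cycle variability.

The generated set per trial is 3 goal channels (endpoint x, y and a
constant tabletop z), 8 efferent channels (the muscles with the largest
activation range over the training conditions) and 16 afferent channels,
sampled at 120 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .signals import SignalBundle

__all__ = [
    "ArmModel",
    "TrialCondition",
    "NoiseOpts",
    "Dataset",
    "DIRECTIONS",
    "AMPLITUDES",
    "FREQUENCIES",
    "make_conditions",
    "minimum_jerk",
    "endpoint_trajectory",
    "inverse_kinematics",
    "forward_kinematics",
    "inverse_dynamics",
    "muscle_kinematics",
    "static_optimisation",
    "select_muscles",
    "generate_trial",
    "generate_natural_transitions",
    "generate_dataset",
]

# direction label -> angle from straight ahead, degrees
DIRECTIONS = {"A": -90.0, "B": -45.0, "C": 0.0, "D": 45.0, "E": 90.0}
AMPLITUDES = (0.25, 0.40)          # m
FREQUENCIES = (1.0, 0.75)          # full cycles per second
TRAIN_DIRECTIONS = ("A", "C", "E")
MORPH_DIRECTIONS = ("B", "D")


def _default_moment_arms() -> np.ndarray:
    # rows: muscles; cols: (shoulder, elbow) moment arms in metres.
    # two mono-articular antagonist pairs per joint plus one bi-articular
    # pair; the second pair at each joint is deliberately weaker so the
    # eight-of-ten selection by activation range is non-trivial.
    return np.array([
        [+0.030, 0.000],   # shoulder flexor
        [-0.030, 0.000],   # shoulder extensor
        [+0.012, 0.000],   # shoulder flexor (weak)
        [-0.022, 0.000],   # shoulder extensor (weak)
        [0.000, +0.028],   # elbow flexor
        [0.000, -0.028],   # elbow extensor
        [0.000, +0.015],   # elbow flexor (weak)
        [0.000, -0.020],   # elbow extensor (weak)
        [+0.025, +0.020],  # bi-articular flexor
        [-0.025, -0.020],  # bi-articular extensor
    ])


def _default_max_forces() -> np.ndarray:
    return np.array([500.0, 500.0, 350.0, 300.0, 450.0, 450.0,
                     250.0, 280.0, 400.0, 400.0])


def _default_rest_lengths() -> np.ndarray:
    return np.array([0.30, 0.30, 0.26, 0.28, 0.28, 0.28, 0.25, 0.26,
                     0.34, 0.34])


@dataclass
class ArmModel:
    """Planar two-link arm with a redundant constant-moment-arm muscle set.

    The shoulder sits at the origin; the central reaching target lies
    ``center_offset`` in front of it.  Muscle length is the affine map
    ``l = l0 - R @ theta`` so a positive moment arm means the muscle
    shortens (and produces positive torque) as its joint angle grows.
    """

    L1: float = 0.33               # upper-arm length, m
    L2: float = 0.45               # forearm+hand length, m
    m1: float = 2.1                # segment masses, kg
    m2: float = 1.65
    c1: float = 0.165              # centre-of-mass distances from proximal joint
    c2: float = 0.225
    I1: float = field(default=2.1 * 0.33 ** 2 / 12.0)   # about segment COM
    I2: float = field(default=1.65 * 0.45 ** 2 / 12.0)
    center_offset: tuple[float, float] = (0.0, 0.30)
    elbow_sign: int = 1
    moment_arms: np.ndarray = field(default_factory=_default_moment_arms)
    max_forces: np.ndarray = field(default_factory=_default_max_forces)
    rest_lengths: np.ndarray = field(default_factory=_default_rest_lengths)
    tabletop_z: float = 0.72       # constant goal z channel, m

    def __post_init__(self) -> None:
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        self.max_forces = np.asarray(self.max_forces, dtype=float)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if self.moment_arms.shape != (self.n_muscles, 2):
            raise ValueError("moment_arms must be (n_muscles, 2)")
        if np.any(self.max_forces <= 0):
            raise ValueError("max forces must be positive")
        for j in range(2):
            col = self.moment_arms[:, j]
            if not (np.any(col > 0) and np.any(col < 0)):
                raise ValueError(f"joint {j} lacks an agonist/antagonist pair")
        self._check_workspace()

    @property
    def n_muscles(self) -> int:
        return len(self.max_forces)

    @property
    def torque_matrix(self) -> np.ndarray:
        """2 x M map from activations to joint torque: tau = B a."""
        return (self.moment_arms * self.max_forces[:, None]).T

    def target_position(self, direction_deg: float, amplitude: float) -> np.ndarray:
        phi = np.deg2rad(direction_deg)
        return (np.asarray(self.center_offset)
                + amplitude * np.array([np.sin(phi), np.cos(phi)]))

    def _check_workspace(self) -> None:
        pts = [np.asarray(self.center_offset)]
        for d in DIRECTIONS.values():
            for A in AMPLITUDES:
                pts.append(self.target_position(d, A))
        lo, hi = abs(self.L1 - self.L2), self.L1 + self.L2
        for p in pts:
            r = float(np.hypot(*p))
            if not (lo + 1e-9 < r < hi - 1e-9):
                raise ValueError(
                    f"target {p} at radius {r:.3f} outside reachable annulus "
                    f"({lo:.3f}, {hi:.3f})")


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the factorial reaching design."""

    direction: str                 # letter A..E
    amplitude: float               # m
    frequency: float               # Hz (full cycle rate)
    n_cycles: int = 10

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def direction_deg(self) -> float:
        return DIRECTIONS[self.direction]

    @property
    def label(self) -> str:
        amp_idx = 1 + AMPLITUDES.index(self.amplitude) if self.amplitude in AMPLITUDES else 0
        return f"{self.direction}{amp_idx}@{self.frequency:g}Hz"


def make_conditions(n_cycles: int = 10) -> list[TrialCondition]:
    """The 20-cell factorial: 5 directions x 2 amplitudes x 2 frequencies."""
    return [TrialCondition(d, A, f, n_cycles)
            for d in DIRECTIONS
            for A in AMPLITUDES
            for f in FREQUENCIES]


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile s(tau) = 10t^3-15t^4+6t^5."""
    tau = np.asarray(tau, dtype=float)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _cycle_displacement(n_samples: int) -> np.ndarray:
    """Out-and-back scalar displacement profile over one cycle (0 -> 1 -> 0)."""
    tau = np.arange(n_samples) / n_samples
    out = tau < 0.5
    s = np.empty(n_samples)
    s[out] = minimum_jerk(2 * tau[out])
    s[~out] = minimum_jerk(2 - 2 * tau[~out])
    return s


def endpoint_trajectory(cond: TrialCondition, fs: float = 120.0,
                        arm: ArmModel | None = None) -> np.ndarray:
    """Goal series for one condition: 3 x T, central target at the origin.

    Each cycle moves out to the peripheral target over the first
    half-period along a minimum-jerk profile and mirrors back, so endpoint
    velocity is zero at both taps.  z is the constant tabletop height
    (relative z = 0 after the origin shift, stored as absolute height so
    the channel is a genuine constant signal).
    """
    if arm is not None:
        # raises if the peripheral target is unreachable
        arm.target_position(cond.direction_deg, cond.amplitude)
    P = fs / cond.frequency
    if abs(P - round(P)) > 1e-9:
        raise ValueError("cycle period must be an integer number of samples")
    P = int(round(P))
    s = np.tile(_cycle_displacement(P), cond.n_cycles) * cond.amplitude
    phi = np.deg2rad(cond.direction_deg)
    xy = np.outer(np.array([np.sin(phi), np.cos(phi)]), s)
    z = np.zeros(xy.shape[1])
    return np.vstack([xy, z])


def forward_kinematics(theta: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Endpoint position(s) (2 x T) from joint angles (2 x T), shoulder frame."""
    th1, th2 = np.atleast_2d(theta)[0], np.atleast_2d(theta)[1]
    x = arm.L1 * np.cos(th1) + arm.L2 * np.cos(th1 + th2)
    y = arm.L1 * np.sin(th1) + arm.L2 * np.sin(th1 + th2)
    return np.vstack([x, y])


def inverse_kinematics(endpoint: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Closed-form two-link IK with a fixed elbow sign.

    ``endpoint`` is 2 x T (or a single 2-vector) in the shoulder frame.
    Raises for points outside the reachable annulus.
    """
    p = np.atleast_2d(np.asarray(endpoint, dtype=float))
    if p.shape[0] != 2:
        p = p.T
    r2 = p[0] ** 2 + p[1] ** 2
    r = np.sqrt(r2)
    lo, hi = abs(arm.L1 - arm.L2), arm.L1 + arm.L2
    if np.any(r > hi + 1e-12) or np.any(r < lo - 1e-12):
        bad = int(np.argmax((r > hi + 1e-12) | (r < lo - 1e-12)))
        raise ValueError(f"unreachable endpoint at sample {bad}: radius {r[bad]:.4f}")
    c2 = (r2 - arm.L1 ** 2 - arm.L2 ** 2) / (2 * arm.L1 * arm.L2)
    c2 = np.clip(c2, -1.0, 1.0)
    th2 = arm.elbow_sign * np.arccos(c2)
    th1 = (np.arctan2(p[1], p[0])
           - np.arctan2(arm.L2 * np.sin(th2), arm.L1 + arm.L2 * np.cos(th2)))
    theta = np.vstack([th1, th2])
    return theta[:, 0] if np.asarray(endpoint).ndim == 1 else theta


def inverse_dynamics(theta: np.ndarray, dtheta: np.ndarray, ddtheta: np.ndarray,
                     arm: ArmModel) -> np.ndarray:
    """Joint torques (2 x T) of the planar two-link arm, no gravity.

    Standard equations of motion tau = M(theta) ddtheta + C(theta, dtheta) dtheta
    for a horizontal (tabletop) plane.
    """
    for a in (theta, dtheta, ddtheta):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite kinematics")
    th2 = np.atleast_2d(theta)[1]
    d1, d2 = np.atleast_2d(dtheta)
    a1, a2 = np.atleast_2d(ddtheta)
    L1, c1, c2m = arm.L1, arm.c1, arm.c2
    m1, m2, I1, I2 = arm.m1, arm.m2, arm.I1, arm.I2
    cos2, sin2 = np.cos(th2), np.sin(th2)
    M11 = I1 + I2 + m1 * c1 ** 2 + m2 * (L1 ** 2 + c2m ** 2 + 2 * L1 * c2m * cos2)
    M12 = I2 + m2 * (c2m ** 2 + L1 * c2m * cos2)
    M22 = I2 + m2 * c2m ** 2
    h = m2 * L1 * c2m * sin2
    tau1 = M11 * a1 + M12 * a2 - h * (2 * d1 * d2 + d2 ** 2)
    tau2 = M12 * a1 + M22 * a2 + h * d1 ** 2
    return np.vstack([tau1, tau2])


def muscle_kinematics(theta: np.ndarray, dtheta: np.ndarray,
                      arm: ArmModel) -> tuple[np.ndarray, np.ndarray]:
    """Muscle lengths and velocities: l = l0 - R theta, v = -R dtheta."""
    theta = np.atleast_2d(theta)
    dtheta = np.atleast_2d(dtheta)
    lengths = arm.rest_lengths[:, None] - arm.moment_arms @ theta
    velocities = -arm.moment_arms @ dtheta
    if np.any(lengths <= 0):
        raise ValueError("non-positive muscle length: arm model misconfigured "
                         "for this workspace")
    return lengths, velocities


def _feasibility_check(B: np.ndarray, tau: np.ndarray) -> None:
    """Raise if no activation vector in [0, 1]^M yields the demanded torque."""
    from scipy.optimize import linprog
    M = B.shape[1]
    res = linprog(np.zeros(M), A_eq=B, b_eq=tau, bounds=[(0, 1)] * M,
                  method="highs")
    if not res.success:
        raise ValueError(f"infeasible torque demand {tau}: outside the "
                         "feasible torque polytope of the muscle set")


def _static_opt_single(B: np.ndarray, tau: np.ndarray,
                       max_iter: int = 60) -> np.ndarray:
    """Active-set solver for min ||a||^2 s.t. B a = tau, 0 <= a <= 1."""
    M = B.shape[1]
    lower = np.zeros(M, dtype=bool)   # clamped at 0
    upper = np.zeros(M, dtype=bool)   # clamped at 1
    for _ in range(max_iter):
        free = ~(lower | upper)
        rhs = tau - B[:, upper] @ np.ones(upper.sum())
        Bf = B[:, free]
        G = Bf @ Bf.T
        try:
            lam = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            lam, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        a = np.zeros(M)
        a[upper] = 1.0
        a[free] = Bf.T @ lam
        # clamp primal violations
        viol_lo = free & (a < -1e-12)
        viol_hi = free & (a > 1 + 1e-12)
        if viol_lo.any() or viol_hi.any():
            lower |= viol_lo
            upper |= viol_hi
            continue
        # KKT check on clamped variables (release at most one per sweep)
        g = B.T @ lam                        # gradient of the dual feasibility
        rel_lo = lower & (g > 1e-10)         # clamped at 0 but wants to rise
        rel_hi = upper & (g < 1 - 1e-10)     # clamped at 1 but wants to drop
        if rel_lo.any():
            lower[np.argmax(np.where(rel_lo, g, -np.inf))] = False
            continue
        if rel_hi.any():
            upper[np.argmin(np.where(rel_hi, g, np.inf))] = False
            continue
        resid = B @ a - tau
        if np.max(np.abs(resid)) > 1e-8:
            _feasibility_check(B, tau)
            break  # feasible but the active set stalled: generic fallback
        return np.clip(a, 0.0, 1.0)
    else:
        _feasibility_check(B, tau)
    # feasible yet not solved by the active set (degenerate geometry):
    # fall back to a generic convex solver
    from scipy.optimize import minimize
    res = minimize(lambda x: np.sum(x ** 2), np.full(M, 0.5),
                   jac=lambda x: 2 * x,
                   constraints=[{"type": "eq", "fun": lambda x: B @ x - tau,
                                 "jac": lambda x: B}],
                   bounds=[(0.0, 1.0)] * M, method="SLSQP",
                   options={"ftol": 1e-16, "maxiter": 500})
    if not res.success or np.max(np.abs(B @ res.x - tau)) > 1e-8:
        raise RuntimeError("static optimisation did not converge")
    return np.clip(res.x, 0.0, 1.0)


def static_optimisation(tau: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Resolve muscle redundancy by minimum sum of squared activations.

    ``tau`` may be a 2-vector (one sample) or 2 x T; the quadratic program
    min sum(a^2) subject to torque equality and 0 <= a <= 1 is solved per
    timestep; the torque residual of every solution is at most 1e-8 N m.
    """
    B = arm.torque_matrix
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 1:
        return _static_opt_single(B, tau)
    T = tau.shape[1]
    out = np.empty((arm.n_muscles, T))
    for t in range(T):
        try:
            out[:, t] = _static_opt_single(B, tau[:, t])
        except ValueError as exc:
            raise ValueError(f"timestep {t}: {exc}") from None
    return out


def select_muscles(activations: np.ndarray, k: int = 8) -> np.ndarray:
    """Indices of the ``k`` muscles with the largest activation range.

    Ties break toward the lower index; the returned indices are sorted
    ascending so channel order is stable.
    """
    activations = np.atleast_2d(activations)
    M = activations.shape[0]
    if M < k:
        raise ValueError(f"need at least {k} muscles, got {M}")
    rng = activations.max(axis=1) - activations.min(axis=1)
    order = sorted(range(M), key=lambda i: (-rng[i], i))
    return np.array(sorted(order[:k]))


@dataclass(frozen=True)
class NoiseOpts:
    """Smooth kinematic jitter emulating human cycle-to-cycle variability.

    White Gaussian endpoint noise is low-pass filtered (4th-order
    Butterworth, ``cutoff_hz``) and rescaled to standard deviation
    ``sigma_endpoint`` per horizontal axis before entering the kinematic
    chain, so every derived signal (angles, torques, activations,
    afference) inherits consistent variability.
    """

    sigma_endpoint: float = 0.002   # m
    cutoff_hz: float = 3.0

    @property
    def enabled(self) -> bool:
        return self.sigma_endpoint > 0


def _smooth_noise(shape: tuple[int, int], fs: float, opts: NoiseOpts,
                  rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(size=shape)
    b, a = butter(4, opts.cutoff_hz / (fs / 2.0))
    sm = filtfilt(b, a, w, axis=-1)
    sm *= opts.sigma_endpoint / max(np.std(sm), 1e-12)
    return sm


def _signals_from_endpoint(xy_goal: np.ndarray, arm: ArmModel,
                           fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the kinematic chain: endpoint -> angles -> torques -> activations."""
    endpoint = xy_goal + np.asarray(arm.center_offset)[:, None]
    theta = inverse_kinematics(endpoint, arm)
    dt = 1.0 / fs
    dtheta = np.gradient(theta, dt, axis=1)
    ddtheta = np.gradient(dtheta, dt, axis=1)
    tau = inverse_dynamics(theta, dtheta, ddtheta, arm)
    act = static_optimisation(tau, arm)
    lengths, velocities = muscle_kinematics(theta, dtheta, arm)
    return act, lengths, velocities


def _bundle_from_goal_xy(xy: np.ndarray, arm: ArmModel, fs: float,
                         cycle_bounds: np.ndarray, meta: dict) -> SignalBundle:
    act, lengths, velocities = _signals_from_endpoint(xy, arm, fs)
    goal = np.vstack([xy, np.full(xy.shape[1], arm.tabletop_z)])
    return SignalBundle(goal=goal, efference=act,
                        afference=np.vstack([lengths, velocities]),
                        fs=fs, cycle_bounds=cycle_bounds, meta=meta)


def generate_trial(cond: TrialCondition, arm: ArmModel | None = None,
                   fs: float = 120.0, seed: int | None = None,
                   noise: NoiseOpts | None = None) -> SignalBundle:
    """One main trial: ``n_cycles`` cyclic reaches of one condition.

    The returned bundle carries the full candidate muscle set
    (``arm.n_muscles`` efferent and ``2 * n_muscles`` afferent channels);
    dataset assembly reduces it to the eight selected muscles.
    """
    arm = arm or ArmModel()
    noise = noise if noise is not None else NoiseOpts()
    goal = endpoint_trajectory(cond, fs, arm)
    xy = goal[:2]
    if noise.enabled:
        rng = np.random.default_rng(seed)
        xy = xy + _smooth_noise(xy.shape, fs, noise, rng)
    P = int(round(fs / cond.frequency))
    bounds = np.arange(cond.n_cycles + 1) * P
    meta = {"condition": cond.label, "direction": cond.direction,
            "amplitude": cond.amplitude, "frequency": cond.frequency,
            "seed": seed}
    return _bundle_from_goal_xy(xy, arm, fs, bounds, meta)


def generate_natural_transitions(arm: ArmModel | None = None, fs: float = 120.0,
                                 seed: int = 0,
                                 noise: NoiseOpts | None = None) -> list[SignalBundle]:
    """The four natural-transition trials: {1, 3} taps x {1.0, 0.75} Hz.

    Each trial visits all ten peripheral targets in a seeded random order,
    returning to the central target between taps; with ``k`` consecutive
    taps a target is reached out-and-back ``k`` times in a row.  Segment
    joins are continuous in position with zero endpoint velocity.
    """
    arm = arm or ArmModel()
    noise = noise if noise is not None else NoiseOpts()
    targets = [(d, A) for d in DIRECTIONS for A in AMPLITUDES]
    ss = np.random.SeedSequence([seed, 7])
    trial_seeds = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(4)]
    bundles = []
    for i, (n_taps, f) in enumerate([(1, 1.0), (1, 0.75), (3, 1.0), (3, 0.75)]):
        rng = np.random.default_rng(trial_seeds[i])
        order = rng.permutation(len(targets))
        P = int(round(fs / f))
        prof = _cycle_displacement(P)
        xy_parts, bounds, off = [], [0], 0
        for j in order:
            d, A = targets[j]
            phi = np.deg2rad(DIRECTIONS[d])
            unit = np.array([np.sin(phi), np.cos(phi)])
            for _ in range(n_taps):
                xy_parts.append(np.outer(unit, prof * A))
                off += P
                bounds.append(off)
        xy = np.hstack(xy_parts)
        if noise.enabled:
            xy = xy + _smooth_noise(xy.shape, fs, noise, rng)
        meta = {"condition": f"NT-{n_taps}tap@{f:g}Hz", "n_taps": n_taps,
                "frequency": f, "order": [targets[j] for j in order],
                "seed": trial_seeds[i]}
        bundles.append(_bundle_from_goal_xy(xy, arm, fs,
                                            np.asarray(bounds), meta))
    return bundles


@dataclass
class Dataset:
    """All trials of one synthetic subject, reduced to the selected muscles."""

    trials: dict[str, SignalBundle]          # 20 main trials by condition label
    natural: list[SignalBundle]              # 4 natural-transition trials
    selection: np.ndarray                    # indices into the candidate muscle set
    arm: ArmModel
    fs: float
    seed: int


def _reduce(bundle: SignalBundle, sel: np.ndarray, n_muscles: int) -> SignalBundle:
    aff_idx = np.concatenate([sel, n_muscles + sel])
    return SignalBundle(goal=bundle.goal, efference=bundle.efference[sel],
                        afference=bundle.afference[aff_idx], fs=bundle.fs,
                        cycle_bounds=bundle.cycle_bounds, meta=bundle.meta)


def generate_dataset(arm: ArmModel | None = None, fs: float = 120.0,
                     seed: int = 0, n_cycles: int = 10,
                     noise: NoiseOpts | None = None,
                     n_selected: int = 8) -> Dataset:
    """Generate the full factorial dataset plus natural-transition trials.

    Muscle selection (largest activation range) is computed on the
    training portion only — cycles 1–6 of the trials in the trained
    directions A, C, E — and then applied to every trial.
    """
    arm = arm or ArmModel()
    noise = noise if noise is not None else NoiseOpts()
    conds = make_conditions(n_cycles)
    ss = np.random.SeedSequence([seed, 1])
    trial_seeds = [int(s.generate_state(1)[0] % 2 ** 31)
                   for s in ss.spawn(len(conds))]
    raw = {c.label: generate_trial(c, arm, fs, trial_seeds[i], noise)
           for i, c in enumerate(conds)}
    train_act = np.hstack([
        raw[c.label].cycles(1, 6).efference
        for c in conds if c.direction in TRAIN_DIRECTIONS])
    sel = select_muscles(train_act, k=n_selected)
    trials = {lbl: _reduce(b, sel, arm.n_muscles) for lbl, b in raw.items()}
    natural = [_reduce(b, sel, arm.n_muscles)
               for b in generate_natural_transitions(arm, fs, seed, noise)]
    return Dataset(trials=trials, natural=natural, selection=sel,
                   arm=arm, fs=fs, seed=seed)
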