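"""FORCE-style recursive least squares training of linear readouts.

The readout of each reservoir is trained online with recursive least
squares (RLS) under teacher forcing: during training every output-feedback
slot is overwritten with the corresponding target signal, corrupted with
i.i.d. Gaussian noise so the trained loop tolerates small output
fluctuations.  Because the forced state trajectory never depends on the
readout, the RLS recursion over a pass is algebraically identical to the
regularised normal-equation (ridge) solution over all samples seen so far;
the default training path exploits this and accumulates cross-moments,
solving at each pass boundary.  The literal per-sample recursion is kept
as ``method="stepwise"`` and the two paths agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reservoir import ReservoirParams

__all__ = [
    "RLSState",
    "TrainConfig",
    "init_rls",
    "rls_update",
    "batch_ridge_oracle",
    "forced_states",
    "train_readout_forced",
]


@dataclass
class RLSState:
    """Inverse-correlation matrix of the RLS recursion, P0 = I / delta."""

    P: np.ndarray
    delta: float

    def symmetrise(self) -> None:
        self.P = 0.5 * (self.P + self.P.T)


@dataclass(frozen=True)
class TrainConfig:
    """Teacher-forced training settings.

    ``n_iterations`` is the number of passes over the training series
    (the inverse-correlation matrix is carried across passes, so extra
    passes behave as extra data).  ``noise_scale`` is the standard
    deviation of the Gaussian noise added to every target-derived signal
    fed to the reservoirs, fresh per channel and sample.  ``delta`` is
    the RLS initialisation scale, equivalently the ridge penalty.
    """

    n_iterations: int = 8
    noise_scale: float = 0.05
    delta: float = 1.0
    seed: int = 0
    method: str = "batch"  # "batch" (normal equations per pass) or "stepwise"
    symmetrise_every: int = 1000

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.method not in ("batch", "stepwise"):
            raise ValueError("method must be 'batch' or 'stepwise'")


def init_rls(n_state: int, delta: float) -> RLSState:
    """P = I / delta; delta plays the role of the ridge penalty."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    return RLSState(P=np.eye(n_state) / delta, delta=delta)


def rls_update(rls: RLSState, W_out: np.ndarray, x: np.ndarray,
               d: np.ndarray) -> tuple[RLSState, np.ndarray]:
    """One RLS step: returns updated (rls, W_out); inputs are not mutated.

    e = W_out x - d;  k = P x / (1 + x' P x);  W_out <- W_out - e k';
    P <- P - k (x' P).
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(d))):
        raise FloatingPointError("non-finite state or target in RLS update")
    Px = rls.P @ x
    denom = 1.0 + x @ Px
    k = Px / denom
    e = W_out @ x - d
    W_new = W_out - np.outer(e, k)
    P_new = rls.P - np.outer(k, Px)
    if not np.all(np.isfinite(P_new)):
        raise FloatingPointError("RLS divergence: non-finite P")
    return RLSState(P=P_new, delta=rls.delta), W_new


def batch_ridge_oracle(states: np.ndarray, targets: np.ndarray,
                       delta: float) -> np.ndarray:
    """Ridge solution W = D X' (X X' + delta I)^-1 that RLS converges to."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    states = np.atleast_2d(states)
    targets = np.atleast_2d(targets)
    N = states.shape[0]
    A = states @ states.T + delta * np.eye(N)
    return np.linalg.solve(A, states @ targets.T).T


def forced_states(params: ReservoirParams, inputs: np.ndarray,
                  feedback: np.ndarray) -> np.ndarray:
    """Teacher-forced state trajectory from a zero initial state.

    ``feedback[:, t]`` is placed directly in the feedback slot at sample
    ``t`` (the caller handles time alignment and noise), so the states
    are independent of any readout.
    """
    inputs = np.atleast_2d(inputs)
    feedback = np.atleast_2d(feedback)
    T = inputs.shape[1]
    if feedback.shape[1] != T:
        raise ValueError("input and feedback lengths differ")
    W, W_in, W_fb, b = params.W, params.W_in, params.W_fb, params.bias
    lam = params.config.leak_rate
    N = params.n_neurons
    # pre-compute the input-driven part in one BLAS call; only the
    # recurrent term needs the sequential loop
    drive = W_in @ inputs + W_fb @ feedback + b[:, None]
    states = np.empty((N, T))
    x = np.zeros(N)
    for t in range(T):
        x = (1.0 - lam) * x + lam * np.tanh(W @ x + drive[:, t])
        states[:, t] = x
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite reservoir state in forced run")
    return states


@dataclass
class TrainLogEntry:
    iteration: int
    channel: int
    rrmse: float


def train_readout_forced(params: ReservoirParams,
                         inputs: np.ndarray,
                         input_noise_rows: np.ndarray,
                         feedback_targets: np.ndarray,
                         regression_targets: np.ndarray,
                         cfg: TrainConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, list[TrainLogEntry]]:
    """Train one reservoir's readout over ``cfg.n_iterations`` forced passes.

    Parameters
    ----------
    inputs
        ``n_in x T`` clean external-input matrix for one pass.
    input_noise_rows
        Boolean mask over input rows: True for target-derived rows that
        receive feedback noise (efference/afference routed as inputs),
        False for recorded signals (the goal window).
    feedback_targets
        ``n_out x T`` values for the feedback slot (already time-aligned:
        column ``t`` is the target at ``t-1``, clamped at the start).
    regression_targets
        ``n_out x T`` clean targets ``d(t)`` for the readout.

    Returns the trained readout and a per-pass, per-channel teacher-forced
    rRMSE log.  The state is reset to zero at the start of every pass and
    noise is drawn fresh per pass, so passes act as additional data.
    """
    T = inputs.shape[1]
    n_out = regression_targets.shape[0]
    N = params.n_neurons
    log: list[TrainLogEntry] = []
    tgt_rng = (np.max(regression_targets, axis=1)
               - np.min(regression_targets, axis=1))
    tgt_rng[tgt_rng == 0] = np.nan  # degenerate channels: log NaN rRMSE

    def noisy(mat, rows=None):
        if cfg.noise_scale == 0:
            return mat
        noise = rng.normal(0.0, cfg.noise_scale, size=mat.shape)
        if rows is not None:
            noise[~rows] = 0.0
        return mat + noise

    if cfg.method == "batch":
        Sxx = np.zeros((N, N))
        Sdx = np.zeros((n_out, N))
        W_out = np.zeros((n_out, N))
        for it in range(cfg.n_iterations):
            X = forced_states(params, noisy(inputs, input_noise_rows),
                              noisy(feedback_targets))
            Sxx += X @ X.T
            Sdx += regression_targets @ X.T
            W_out = np.linalg.solve(Sxx + cfg.delta * np.eye(N), Sdx.T).T
            err = W_out @ X - regression_targets
            rr = np.sqrt(np.mean(err ** 2, axis=1)) / tgt_rng
            log.extend(TrainLogEntry(it + 1, c, float(rr[c])) for c in range(n_out))
        return W_out, log

    # literal per-sample recursion (verification / ablation path)
    rls = init_rls(N, cfg.delta)
    W_out = np.zeros((n_out, N))
    n_steps = 0
    for it in range(cfg.n_iterations):
        X = forced_states(params, noisy(inputs, input_noise_rows),
                          noisy(feedback_targets))
        for t in range(T):
            rls, W_out = rls_update(rls, W_out, X[:, t], regression_targets[:, t])
            n_steps += 1
            if cfg.symmetrise_every and n_steps % cfg.symmetrise_every == 0:
                rls.symmetrise()
        err = W_out @ X - regression_targets
        rr = np.sqrt(np.mean(err ** 2, axis=1)) / tgt_rng
        log.extend(TrainLogEntry(it + 1, c, float(rr[c])) for c in range(n_out))
    return W_out, log
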