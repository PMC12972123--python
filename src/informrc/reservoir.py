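"""Leaky echo state network core.

A reservoir is a fixed, sparse random recurrent network with a trainable
linear readout.  Stability of the autonomous dynamics is governed by the
spectral radius of the recurrent matrix; responsiveness to inputs and to
output feedback by the corresponding scaling factors.  State propagation
uses the standard leaky-tanh update

    x(t) = (1 - lam) * x(t-1) + lam * tanh(W x(t-1) + W_in u(t) + W_fb y(t-1) + b)

with the readout linear in the state, y(t) = W_out x(t).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigs as sparse_eigs

__all__ = [
    "ReservoirConfig",
    "ReservoirParams",
    "ReservoirState",
    "init_reservoir",
    "step",
    "run_sequence",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class ReservoirConfig:
    """Hyperparameters of a single echo state network.

    Parameters
    ----------
    n_neurons
        Reservoir size N.
    spectral_radius
        Target largest absolute eigenvalue of the recurrent matrix (> 0).
    connectivity
        Fraction of nonzero recurrent weights, in (0, 1].
    input_scaling
        Half-width of the uniform distribution for input weights (>= 0).
    feedback_scaling
        Half-width of the uniform distribution for output-feedback weights.
    leak_rate
        Leak coefficient lambda in (0, 1]; 1 recovers the plain tanh ESN.
    bias_scaling
        Half-width of the uniform bias draw; 0 gives a zero bias vector.
    seed
        Seed for all random draws; identical seeds give bit-identical matrices.
    """

    n_neurons: int = 300
    spectral_radius: float = 0.9
    connectivity: float = 0.1
    input_scaling: float = 1.0
    feedback_scaling: float = 1.0
    leak_rate: float = 1.0
    bias_scaling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not (0.0 < self.leak_rate <= 1.0):
            raise ValueError("leak_rate must lie in (0, 1]")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be > 0")
        if not (0.0 < self.connectivity <= 1.0):
            raise ValueError("connectivity must lie in (0, 1]")
        if self.input_scaling < 0 or self.feedback_scaling < 0:
            raise ValueError("scalings must be >= 0")

    def replace(self, **kw) -> "ReservoirConfig":
        d = asdict(self)
        d.update(kw)
        return ReservoirConfig(**d)


@dataclass
class ReservoirParams:
    """Fixed random matrices of one reservoir plus its configuration."""

    W: sp.csr_matrix          # N x N recurrent, rescaled to the target spectral radius
    W_in: np.ndarray          # N x n_in
    W_fb: np.ndarray          # N x n_out
    bias: np.ndarray          # N
    config: ReservoirConfig

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.W_fb.shape[1]


@dataclass
class ReservoirState:
    """Activation vector and sample index (time in units of 1/fs)."""

    x: np.ndarray
    t: int = 0


def _spectral_radius(W: sp.spmatrix) -> float:
    n = W.shape[0]
    if n <= 300:
        # dense eig is cheap here and accurate to machine precision
        return float(np.max(np.abs(np.linalg.eigvals(W.toarray()))))
    try:
        vals = sparse_eigs(W.astype(float), k=1, which="LM",
                           return_eigenvectors=False, maxiter=n * 50, tol=1e-12)
        return float(np.abs(vals[0]))
    except Exception:
        return float(np.max(np.abs(np.linalg.eigvals(W.toarray()))))


def init_reservoir(config: ReservoirConfig, n_in: int, n_out: int) -> ReservoirParams:
    """Draw the fixed random matrices of a reservoir.

    The recurrent matrix gets ``ceil(connectivity * N**2)`` nonzeros drawn
    uniformly on [-1, 1] and is rescaled so that its largest absolute
    eigenvalue equals ``spectral_radius`` exactly.  Input and feedback
    matrices are dense uniform draws on [-scaling, +scaling].

    Raises
    ------
    ValueError
        If dimensions are non-positive or the raw draw has (numerically)
        zero spectral radius so the rescaling is undefined.
    """
    if n_in < 0 or n_out < 0:
        raise ValueError("n_in and n_out must be non-negative")
    N = config.n_neurons
    rng = np.random.default_rng(config.seed)

    nnz = int(np.ceil(config.connectivity * N * N))
    flat = rng.choice(N * N, size=nnz, replace=False)
    vals = rng.uniform(-1.0, 1.0, size=nnz)
    W = sp.csr_matrix((vals, (flat // N, flat % N)), shape=(N, N))
    rho0 = _spectral_radius(W)
    if rho0 < 1e-12:
        raise ValueError(
            "raw recurrent draw has numerically zero spectral radius; "
            "retry with a different seed or higher connectivity"
        )
    W = (W * (config.spectral_radius / rho0)).tocsr()

    W_in = rng.uniform(-config.input_scaling, config.input_scaling, size=(N, n_in))
    W_fb = rng.uniform(-config.feedback_scaling, config.feedback_scaling, size=(N, n_out))
    bias = (rng.uniform(-config.bias_scaling, config.bias_scaling, size=N)
            if config.bias_scaling > 0 else np.zeros(N))
    return ReservoirParams(W=W, W_in=W_in, W_fb=W_fb, bias=bias, config=config)


def step(params: ReservoirParams, state: ReservoirState,
         u: np.ndarray, y_fb: np.ndarray,
         leak_rate: float | None = None) -> ReservoirState:
    """Advance the reservoir by one sample.

    ``u`` is the external input at the new sample, ``y_fb`` the output
    feedback (previous output, or its overwrite).  Returns a new state;
    the input state is not modified.
    """
    lam = params.config.leak_rate if leak_rate is None else leak_rate
    u = np.asarray(u, dtype=float)
    y_fb = np.asarray(y_fb, dtype=float)
    if u.shape != (params.n_in,):
        raise ValueError(f"input dimension {u.shape} != ({params.n_in},)")
    if y_fb.shape != (params.n_out,):
        raise ValueError(f"feedback dimension {y_fb.shape} != ({params.n_out},)")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(y_fb))):
        raise ValueError("non-finite input or feedback")
    pre = params.W @ state.x + params.W_in @ u + params.W_fb @ y_fb + params.bias
    x_new = (1.0 - lam) * state.x + lam * np.tanh(pre)
    return ReservoirState(x=x_new, t=state.t + 1)


def run_sequence(params: ReservoirParams, W_out: np.ndarray,
                 inputs: np.ndarray,
                 feedback_overwrite: np.ndarray | None = None,
                 leak_rate: float | None = None,
                 x0: np.ndarray | None = None,
                 fb0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Run the reservoir over a whole input sequence.

    Parameters
    ----------
    inputs
        ``n_in x T`` external input matrix.
    feedback_overwrite
        Optional ``n_out x T`` matrix; when given, the feedback slot at
        sample ``t`` carries ``feedback_overwrite[:, t-1]`` (teacher
        forcing / external drive) instead of the network's own previous
        output.  When absent the loop is closed: ``y(t-1)`` is fed back.
    fb0
        Feedback used at the first sample (default zeros).

    Returns
    -------
    (states, outputs)
        ``N x T`` state trajectory and ``n_out x T`` readout outputs,
        with ``outputs[:, t] = W_out @ states[:, t]``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = inputs.shape[1]
    if T == 0:
        raise ValueError("empty input sequence")
    if feedback_overwrite is not None:
        feedback_overwrite = np.atleast_2d(np.asarray(feedback_overwrite, dtype=float))
        if feedback_overwrite.shape[1] != T:
            raise ValueError("feedback_overwrite length must equal input length")
    lam = params.config.leak_rate if leak_rate is None else leak_rate
    N = params.n_neurons
    states = np.empty((N, T))
    outputs = np.empty((params.n_out, T))
    x = np.zeros(N) if x0 is None else np.asarray(x0, dtype=float).copy()
    y_prev = np.zeros(params.n_out) if fb0 is None else np.asarray(fb0, dtype=float)
    W, W_in, W_fb, b = params.W, params.W_in, params.W_fb, params.bias
    for t in range(T):
        fb = y_prev if feedback_overwrite is None else (
            feedback_overwrite[:, t - 1] if t > 0 else y_prev)
        x = (1.0 - lam) * x + lam * np.tanh(W @ x + W_in @ inputs[:, t] + W_fb @ fb + b)
        y = W_out @ x
        states[:, t] = x
        outputs[:, t] = y
        y_prev = y
    return states, outputs


def save_params(path, params: ReservoirParams, W_out: np.ndarray | None = None) -> None:
    """Serialise a reservoir (and optionally its readout) to an NPZ container.

    The configuration is embedded as a JSON block so the round trip is
    bit-exact and self-describing.
    """
    W = params.W.tocoo()
    arrays = dict(
        W_data=W.data, W_row=W.row, W_col=W.col,
        W_shape=np.array(W.shape),
        W_in=params.W_in, W_fb=params.W_fb, bias=params.bias,
        config_json=np.frombuffer(
            json.dumps(asdict(params.config)).encode(), dtype=np.uint8),
    )
    if W_out is not None:
        arrays["W_out"] = np.asarray(W_out)
    np.savez(path, **arrays)


def load_params(path) -> tuple[ReservoirParams, np.ndarray | None]:
    with np.load(path) as z:
        cfg = ReservoirConfig(**json.loads(bytes(z["config_json"]).decode()))
        W = sp.csr_matrix((z["W_data"], (z["W_row"], z["W_col"])),
                          shape=tuple(z["W_shape"]))
        params = ReservoirParams(W=W, W_in=z["W_in"], W_fb=z["W_fb"],
                                 bias=z["bias"], config=cfg)
        W_out = z["W_out"] if "W_out" in z else None
    return params, W_out
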