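"""State-space sequence engine.

A linear state-space model (SSM) maps an input sequence ``x`` to an output
``y`` through a latent state ``h``:

    h'(t) = A h(t) + B x(t),        y(t) = C h(t)

Discretized with the bilinear transform at step size ``delta`` this becomes
the recurrence

    h[n] = A_bar h[n-1] + B_bar x[n],   y[n] = C h[n]

with ``A_bar = (I - d/2 A)^-1 (I + d/2 A)`` and ``B_bar = (I - d/2 A)^-1 d B``.
For fixed matrices the recurrence is equivalent to a causal convolution with
kernel ``K[j] = C A_bar^j B_bar``.  The selective variant re-discretizes at
every token from input-dependent ``B``, ``C`` and ``delta`` (shared diagonal
``A``), which is what gives the model content-dependent dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import linear_recurrence

__all__ = [
    "SSMParams",
    "DiscreteSSM",
    "SelectiveParams",
    "DiscretizationError",
    "discretize",
    "ssm_recurrence",
    "ssm_convolution",
    "selective_scan",
]


class DiscretizationError(ValueError):
    """Raised when ``(I - delta/2 A)`` is singular."""


@dataclass
class SSMParams:
    """Continuous LTI system (A, B, C) with step size ``delta``.

    ``A`` may be a full ``(N, N)`` matrix or a length-``N`` diagonal.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: float

    def __post_init__(self):
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(-1)
        self.C = np.asarray(self.C, dtype=float).reshape(-1)
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        n = self.B.size
        if n < 1 or self.C.size != n:
            raise ValueError("B and C must have equal length >= 1")
        if self.A.ndim == 1:
            if self.A.size != n:
                raise ValueError("diagonal A length must match B")
        elif self.A.shape != (n, n):
            raise ValueError(f"A must be ({n},{n}) or length-{n} diagonal")

    @property
    def n_state(self) -> int:
        return self.B.size

    @property
    def diagonal(self) -> bool:
        return self.A.ndim == 1


@dataclass
class DiscreteSSM:
    """Bilinear-discretized system ``(A_bar, B_bar, C_bar)``."""

    A_bar: np.ndarray
    B_bar: np.ndarray
    C_bar: np.ndarray

    @property
    def diagonal(self) -> bool:
        return self.A_bar.ndim == 1


def discretize(p: SSMParams) -> DiscreteSSM:
    """Bilinear (Tustin) discretization of a continuous system."""
    d = p.delta
    if p.diagonal:
        den = 1.0 - 0.5 * d * p.A
        if np.any(den == 0.0):
            raise DiscretizationError("(I - delta/2 A) is singular")
        a_bar = (1.0 + 0.5 * d * p.A) / den
        b_bar = d * p.B / den
        return DiscreteSSM(a_bar, b_bar, p.C.copy())
    n = p.n_state
    M = np.eye(n) - 0.5 * d * p.A
    if abs(np.linalg.det(M)) < 1e-300:
        raise DiscretizationError("(I - delta/2 A) is singular")
    Minv = np.linalg.inv(M)
    a_bar = Minv @ (np.eye(n) + 0.5 * d * p.A)
    b_bar = Minv @ (d * p.B)
    return DiscreteSSM(a_bar, b_bar, p.C.copy())


def ssm_recurrence(d: DiscreteSSM, x: np.ndarray) -> np.ndarray:
    """Run the stepwise recurrence over a scalar input sequence."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size < 1:
        raise ValueError("sequence must have length >= 1")
    n = d.B_bar.size
    h = np.zeros(n)
    y = np.empty(x.size)
    for i, xi in enumerate(x):
        if d.diagonal:
            h = d.A_bar * h + d.B_bar * xi
        else:
            h = d.A_bar @ h + d.B_bar * xi
        y[i] = d.C_bar @ h
    return y


def ssm_kernel(d: DiscreteSSM, length: int) -> np.ndarray:
    """Truncated convolution kernel ``K[j] = C A_bar^j B_bar``."""
    K = np.empty(length)
    v = d.B_bar.copy()
    for j in range(length):
        K[j] = d.C_bar @ v
        v = d.A_bar * v if d.diagonal else d.A_bar @ v
    return K


def ssm_convolution(d: DiscreteSSM, x: np.ndarray) -> np.ndarray:
    """Evaluate the LTI system as a causal convolution ``y = K * x``."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size < 1:
        raise ValueError("sequence must have length >= 1")
    K = ssm_kernel(d, x.size)
    return np.convolve(K, x)[: x.size]


# ---------------------------------------------------------------------------
# Selective (input-dependent) scan


@dataclass
class SelectiveParams:
    """Projections making B, C and delta functions of each input token.

    For a token ``x_n`` of dimension ``d``:

        B_n     = W_B  x_n + b_B            (length N)
        C_n     = W_C  x_n + b_C            (length N)
        delta_n = softplus(W_dt x_n + b_dt) (length d, per-channel step)

    ``A`` is shared across tokens and stored as a per-channel diagonal
    ``(d, N)`` with negative real entries, so the bilinear inverse is
    elementwise.  The softplus keeps every activated step size positive.
    """

    A: np.ndarray          # (d, N) negative diagonal entries
    W_B: np.ndarray        # (N, d)
    b_B: np.ndarray        # (N,)
    W_C: np.ndarray        # (N, d)
    b_C: np.ndarray        # (N,)
    W_dt: np.ndarray       # (d, d)
    b_dt: np.ndarray       # (d,)

    def __post_init__(self):
        for name in ("A", "W_B", "b_B", "W_C", "b_C", "W_dt", "b_dt"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.A >= 0):
            raise ValueError("shared A must have strictly negative diagonal")

    @property
    def d_model(self) -> int:
        return self.A.shape[0]

    @property
    def n_state(self) -> int:
        return self.A.shape[1]

    @classmethod
    def init(cls, d: int, n_state: int, rng: np.random.Generator,
             c_scale: float = 1.0) -> "SelectiveParams":
        """Standard initialization: A = -(1..N) per channel, dt in [1e-3, 0.1]."""
        A = -np.tile(np.arange(1.0, n_state + 1.0), (d, 1))
        W_B = rng.normal(0.0, d**-0.5, (n_state, d))
        W_C = rng.normal(0.0, d**-0.5, (n_state, d)) * c_scale
        dt = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), d))
        b_dt = dt + np.log(-np.expm1(-dt))  # inverse softplus
        return cls(A, W_B, np.zeros(n_state), W_C, np.zeros(n_state),
                   np.zeros((d, d)), b_dt)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def selective_discretize(
    sp: SelectiveParams, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-token bilinear discretization.

    ``X`` has shape ``(..., L, d)``; returns ``a_bar, b_u`` of shape
    ``(..., L, d, N)`` (``b_u`` already multiplied by the token value) and
    ``C`` of shape ``(..., L, N)``.
    """
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X).all(axis=-1))
        raise FloatingPointError(f"non-finite token at index {tuple(bad[0])}")
    B = X @ sp.W_B.T + sp.b_B                      # (..., L, N)
    C = X @ sp.W_C.T + sp.b_C                      # (..., L, N)
    dt = softplus(X @ sp.W_dt.T + sp.b_dt)         # (..., L, d)
    if not (np.all(np.isfinite(B)) and np.all(np.isfinite(C)) and np.all(np.isfinite(dt))):
        raise FloatingPointError("non-finite projection output")
    half = 0.5 * dt[..., None] * sp.A              # (..., L, d, N)
    den = 1.0 - half
    a_bar = (1.0 + half) / den
    b_bar = dt[..., None] * B[..., None, :] / den  # (..., L, d, N)
    b_u = b_bar * X[..., None]
    return a_bar, b_u, C


def selective_scan(sp: SelectiveParams, X: np.ndarray) -> np.ndarray:
    """Input-dependent SSM over a token sequence.

    ``X`` has shape ``(L, d)`` or ``(S, L, d)`` for a batch of ``S``
    equal-length sequences; the scan runs along ``L`` independently per
    channel with the token's own discretized system.  Output shape equals
    input shape.
    """
    X = np.asarray(X, dtype=float)
    batched = X.ndim == 3
    if not batched:
        X = X[None]
    S, L, d = X.shape
    a_bar, b_u, C = selective_discretize(sp, X)
    # scan along L: move it to axis 0
    h = linear_recurrence(
        np.moveaxis(a_bar, 1, 0).reshape(L, -1),
        np.moveaxis(b_u, 1, 0).reshape(L, -1),
    ).reshape((L, S, d, sp.n_state))
    y = np.einsum("lsdn,sln->sld", h, C)
    return y if batched else y[0]
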