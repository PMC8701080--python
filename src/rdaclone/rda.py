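"""Extended robust deep autoencoder: masked low-rank + sparse decomposition.

The observed genotype matrix X is split as X = LD + S, where LD is the
nonlinear low-rank part (the reconstruction of a deep autoencoder trained on
its own rows, one row per cell) and S is a sparse error matrix.  The l1
penalty λ‖PΩS‖₁ is restricted to the observed index set Ω, so entries of S
outside Ω are free parameters: missing genotype calls are imputed through
the low-rank part rather than being penalised as errors.

The optimisation alternates, ADMM-style:

    LD ← X − S
    θ  ← argmin_θ ‖LD − D_θ(E_θ(LD))‖²     (a few stochastic epochs, warm start)
    LD ← D_θ(E_θ(LD))
    S  ← X − LD;  PΩS ← soft-threshold(PΩS, λ)

with convergence monitored through the normalised residuals
c1 = ‖X−LD−S‖_F/‖X‖_F and c2 = ‖LS−LD−S‖_F/‖X‖_F (LS = LD+S from the
previous sweep).  The recovered matrix is binarised at 0.5 into genotype
calls; a sigmoid output layer makes each LD entry a per-entry mutation
probability.

No GPU or autodiff framework is required: the autoencoder is a small fully
connected network with hand-written backpropagation and Adam updates, which
is ample at the matrix sizes this tool targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import DegenerateInputError

logger = logging.getLogger(__name__)

#: Sentinel for "derive λ from the matrix shape" (1/sqrt(max(n, m))).
AUTO = "auto"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_encoder_widths(m: int) -> tuple[int, ...]:
    """Symmetric-autoencoder encoder widths for an m-site matrix.

    Two hidden layers narrowing into a bottleneck of max(8, m/8) features,
    clamped so the bottleneck is a strict compression.
    """
    bottleneck = max(8, math.ceil(m / 8))
    bottleneck = max(1, min(bottleneck, m - 1))
    return (min(512, m), min(128, m), bottleneck)


@dataclass
class AutoencoderSpec:
    """Architecture and training hyper-parameters of the autoencoder.

    encoder_widths ends in the bottleneck width; the decoder mirrors the
    encoder.  batch_cells fixes the number of cells per stochastic step
    (clamped to n at run time), which keeps the per-iteration cost flat as
    the matrix grows.
    """

    encoder_widths: tuple[int, ...] | None = None
    activation: str = "tanh"
    output_activation: str = "sigmoid"
    inner_epochs: int = 30
    batch_cells: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError(
                f"unknown output activation {self.output_activation!r}"
            )
        for name in ("inner_epochs", "batch_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def resolve_widths(self, m: int) -> tuple[int, ...]:
        widths = self.encoder_widths or default_encoder_widths(m)
        if widths[-1] >= m and m > 1:
            raise ValueError(
                f"bottleneck width {widths[-1]} must be smaller than the "
                f"number of sites {m}"
            )
        return tuple(widths)


@dataclass
class RDAConfig:
    """Decomposition-level knobs: sparsity weight, stopping rule, binarisation."""

    lam: float | str = AUTO
    epsilon: float = 1e-6
    max_outer_iters: int = 30
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.lam != AUTO and (not np.isreal(self.lam) or self.lam <= 0):
            raise ValueError("lam must be positive or AUTO")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must lie in (0, 1)")


@dataclass
class DecompositionResult:
    """Output bundle of :func:`decompose`."""

    LD: np.ndarray
    S: np.ndarray
    LS: np.ndarray
    trace: list[tuple[float, float]]
    nnz_trace: list[int]
    genotype_calls: np.ndarray
    converged: bool
    iterations_run: int
    lam: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def project_omega(M: np.ndarray, omega_mask: np.ndarray) -> np.ndarray:
    """PΩ: keep observed entries, zero the rest."""
    M = np.asarray(M, dtype=np.float64)
    omega_mask = np.asarray(omega_mask, dtype=np.float64)
    if M.shape != omega_mask.shape:
        raise ValueError(
            f"shape mismatch: matrix {M.shape} vs mask {omega_mask.shape}"
        )
    return M * omega_mask


def shrink(S: np.ndarray, lam: float, omega_mask: np.ndarray) -> np.ndarray:
    """Soft-threshold the observed entries of S by λ; leave Ω̄ untouched.

    The proximal operator of λ‖PΩ·‖₁: observed entries move toward zero by
    λ (to exactly zero when |s| ≤ λ); unobserved entries carry the
    imputation residual and are returned unchanged.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    S = np.asarray(S, dtype=np.float64)
    omega_mask = np.asarray(omega_mask, dtype=np.float64)
    if S.shape != omega_mask.shape:
        raise ValueError(
            f"shape mismatch: matrix {S.shape} vs mask {omega_mask.shape}"
        )
    soft = np.sign(S) * np.maximum(np.abs(S) - lam, 0.0)
    return np.where(omega_mask > 0, soft, S)


def binarize(LD: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Discretise the recovered matrix into {0,1} calls (1 iff entry ≥ threshold)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(LD) >= threshold).astype(np.int8)


def auto_lambda(n: int, m: int) -> float:
    """Default sparsity weight 1/sqrt(max(n, m)), the robust-decomposition convention."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    return 1.0 / math.sqrt(max(n, m))


# ---------------------------------------------------------------------------
# the autoencoder (numpy MLP, Adam)
# ---------------------------------------------------------------------------

def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        # clip to keep exp in range; gradients unaffected at these magnitudes
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    return z  # linear


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a * a
    if name == "sigmoid":
        return a * (1.0 - a)
    return np.ones_like(z)


class AutoencoderState:
    """Parameters θ and Adam moments of the symmetric autoencoder.

    Layer widths run m → encoder_widths → reversed hidden widths → m; all
    hidden layers share one activation, the output layer its own.
    """

    def __init__(self, m: int, spec: AutoencoderSpec):
        enc = spec.resolve_widths(m)
        widths = [m, *enc, *reversed(enc[:-1]), m]
        self.widths = widths
        self.activations = [spec.activation] * (len(widths) - 2) + [
            spec.output_activation
        ]
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xAE])
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.mW = [np.zeros_like(w) for w in self.W]
        self.vW = [np.zeros_like(w) for w in self.W]
        self.mb = [np.zeros_like(b) for b in self.b]
        self.vb = [np.zeros_like(b) for b in self.b]
        self.t = 0  # Adam step counter

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, keep: bool = False):
        zs, acts = [], [x]
        a = x
        for W, b, name in zip(self.W, self.b, self.activations):
            z = a @ W + b
            a = _act(name, z)
            if keep:
                zs.append(z)
                acts.append(a)
        return (a, zs, acts) if keep else a

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def train_step(self, batch: np.ndarray, lr: float) -> float:
        """One Adam step on the mean-squared reconstruction loss of a batch."""
        y, zs, acts = self.forward(batch, keep=True)
        diff = y - batch
        loss = float(np.mean(diff * diff))
        if not np.isfinite(loss):
            raise FloatingPointError(
                "non-finite autoencoder loss; consider lowering learning_rate"
            )
        delta = (2.0 / diff.size) * diff
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        for layer in range(len(self.W) - 1, -1, -1):
            delta = delta * _act_grad(
                self.activations[layer], zs[layer], acts[layer + 1]
            )
            gW[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.W[layer].T
        self._adam(gW, gb, lr)
        return loss

    def _adam(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        corr1 = 1.0 - beta1 ** self.t
        corr2 = 1.0 - beta2 ** self.t
        for i in range(len(self.W)):
            self.mW[i] = beta1 * self.mW[i] + (1 - beta1) * gW[i]
            self.vW[i] = beta2 * self.vW[i] + (1 - beta2) * gW[i] ** 2
            self.W[i] -= lr * (self.mW[i] / corr1) / (
                np.sqrt(self.vW[i] / corr2) + eps
            )
            self.mb[i] = beta1 * self.mb[i] + (1 - beta1) * gb[i]
            self.vb[i] = beta2 * self.vb[i] + (1 - beta2) * gb[i] ** 2
            self.b[i] -= lr * (self.mb[i] / corr1) / (
                np.sqrt(self.vb[i] / corr2) + eps
            )


def refit_autoencoder(
    LD: np.ndarray,
    spec: AutoencoderSpec,
    state: AutoencoderState | None = None,
    iteration: int = 0,
) -> tuple[AutoencoderState, np.ndarray]:
    """Refit θ on the rows of LD and return (θ', reconstruction of every row).

    Runs ``spec.inner_epochs`` passes of minibatch Adam (``spec.batch_cells``
    cells per step) warm-starting from the incoming state.  Deterministic
    given (spec.seed, iteration): the batch shuffle stream is derived from
    both.
    """
    LD = np.asarray(LD, dtype=np.float64)
    n, m = LD.shape
    if state is None:
        state = AutoencoderState(m, spec)
    batch = min(spec.batch_cells, n)
    rng = np.random.default_rng(
        [spec.seed & 0x7FFFFFFF, iteration & 0x7FFFFFFF, 0x5B]
    )
    for _ in range(spec.inner_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            state.train_step(LD[idx], spec.learning_rate)
    return state, state.reconstruct(LD)


# ---------------------------------------------------------------------------
# the alternating decomposition
# ---------------------------------------------------------------------------

def decompose(
    X: np.ndarray,
    omega_mask: np.ndarray,
    cfg: RDAConfig | None = None,
    spec: AutoencoderSpec | None = None,
) -> DecompositionResult:
    """Run the alternating masked low-rank + sparse decomposition of X.

    X must be zero-filled at unobserved entries (see ``encode_for_rda``).
    Returns the recovered matrix LD, the sparse matrix S, the convergence
    trace of (c1, c2), and binarised genotype calls.
    """
    cfg = cfg or RDAConfig()
    spec = spec or AutoencoderSpec()
    X = np.asarray(X, dtype=np.float64)
    omega_mask = np.asarray(omega_mask, dtype=np.float64)
    if X.shape != omega_mask.shape:
        raise ValueError("X and omega_mask shapes differ")
    n, m = X.shape
    norm_X = float(np.linalg.norm(X))
    if norm_X == 0.0:
        raise DegenerateInputError("‖X‖ = 0: nothing to decompose")
    lam = auto_lambda(n, m) if cfg.lam == AUTO else float(cfg.lam)

    S = np.zeros_like(X)
    LS = X.copy()
    state: AutoencoderState | None = None
    trace: list[tuple[float, float]] = []
    nnz_trace: list[int] = []
    converged = False
    iterations = 0

    for it in range(cfg.max_outer_iters):
        iterations = it + 1
        LD = X - S
        state, LD = refit_autoencoder(LD, spec, state, iteration=it)
        S = X - LD
        S = shrink(S, lam, omega_mask)
        resid = X - LD - S
        c1 = float(np.linalg.norm(resid)) / norm_X
        c2 = float(np.linalg.norm(LS - LD - S)) / norm_X
        trace.append((c1, c2))
        nnz_trace.append(int(np.count_nonzero(S * omega_mask)))
        logger.info("outer iter %d: c1=%.3e c2=%.3e nnz(PΩS)=%d",
                    iterations, c1, c2, nnz_trace[-1])
        if c1 < cfg.epsilon or c2 < cfg.epsilon:
            converged = True
            break
        LS = LD + S

    if not converged:
        logger.warning(
            "decomposition hit the iteration cap (%d) without meeting "
            "epsilon=%.1e; returning the last iterate",
            cfg.max_outer_iters, cfg.epsilon,
        )

    calls = binarize(LD, cfg.binarize_threshold)
    return DecompositionResult(
        LD=LD,
        S=S,
        LS=LS,
        trace=trace,
        nnz_trace=nnz_trace,
        genotype_calls=calls,
        converged=converged,
        iterations_run=iterations,
        lam=lam,
    )
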