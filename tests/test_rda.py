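"""The masked low-rank + sparse decomposition and its building blocks."""

import numpy as np
import pytest

from rdaclone import (
    AutoencoderSpec,
    RDAConfig,
    auto_lambda,
    binarize,
    decompose,
    project_omega,
    refit_autoencoder,
    shrink,
)
from rdaclone.io import DegenerateInputError

FAST_SPEC = dict(inner_epochs=10, seed=3)


# -- projection --------------------------------------------------------------

def test_project_omega_definition():
    M = np.array([[1, 0.5], [0.2, 1]])
    mask = np.array([[1, 0], [0, 1]])
    assert project_omega(M, mask).tolist() == [[1, 0], [0, 1]]
    assert np.array_equal(project_omega(M, np.ones_like(M)), M)


def test_project_omega_idempotent(rng):
    M, mask = rng.normal(size=(5, 4)), rng.integers(0, 2, size=(5, 4))
    once = project_omega(M, mask)
    assert np.array_equal(project_omega(once, mask), once)


def test_project_omega_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        project_omega(np.zeros((2, 2)), np.zeros((3, 2)))


# -- soft-thresholding -------------------------------------------------------

def test_shrink_examples():
    mask = np.ones((1, 1))
    assert shrink(np.array([[0.8]]), 0.3, mask)[0, 0] == pytest.approx(0.5)
    assert shrink(np.array([[-0.2]]), 0.3, mask)[0, 0] == 0.0
    # unobserved entries are untouched whatever lambda
    assert shrink(np.array([[-0.7]]), 5.0, np.zeros((1, 1)))[0, 0] == -0.7


def test_shrink_is_prox_of_l1_grid_search(rng):
    """Soft-thresholding minimises (1/2)(x-s)^2 + lam*|x| (scalar oracle)."""
    lam = 0.3
    grid = np.linspace(-4, 4, 16001)
    for s in rng.uniform(-3, 3, size=100):
        objective = 0.5 * (grid - s) ** 2 + lam * np.abs(grid)
        best = grid[np.argmin(objective)]
        got = shrink(np.array([[s]]), lam, np.ones((1, 1)))[0, 0]
        assert got == pytest.approx(best, abs=1e-3)


def test_shrink_rejects_nonpositive_lambda():
    with pytest.raises(ValueError):
        shrink(np.zeros((2, 2)), 0.0, np.ones((2, 2)))


# -- binarisation and lambda default ----------------------------------------

@pytest.mark.parametrize("value, expected", [(0.7, 1), (0.5, 1), (-0.1, 0)])
def test_binarize_rule(value, expected):
    assert binarize(np.array([[value]]), 0.5)[0, 0] == expected


def test_auto_lambda():
    assert auto_lambda(100, 100) == pytest.approx(0.1)
    assert auto_lambda(3000, 1000) == pytest.approx(1 / np.sqrt(3000))
    vals = [auto_lambda(n, 10) for n in (10, 100, 1000, 5000)]
    assert vals == sorted(vals, reverse=True)


# -- autoencoder refit -------------------------------------------------------

def test_refit_reduces_reconstruction_loss(two_clone_block):
    """Averaged over seeds, a refit pass does not worsen the fit."""
    X, _ = two_clone_block
    deltas = []
    for seed in (0, 1, 2):
        spec = AutoencoderSpec(inner_epochs=10, seed=seed)
        state, recon0 = refit_autoencoder(X, spec, iteration=0)
        loss0 = np.mean((recon0 - X) ** 2)
        state, recon1 = refit_autoencoder(X, spec, state, iteration=1)
        loss1 = np.mean((recon1 - X) ** 2)
        deltas.append(loss1 - loss0)
    assert np.mean(deltas) <= 1e-4


def test_refit_rank_one_input_reconstructs():
    """Identical rows are representable by any bottleneck >= 1."""
    row = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
    X = np.tile(row, (30, 1))
    # 30 cells fit in one batch, so each epoch is a single Adam step;
    # a larger step size compensates for the small step count
    spec = AutoencoderSpec(learning_rate=1e-2, seed=1)
    state, recon = refit_autoencoder(X, spec)
    for i in range(1, 5):
        state, recon = refit_autoencoder(X, spec, state, iteration=i)
    assert np.abs(recon - X).max() < 0.05


def test_refit_output_shape(rng):
    X = rng.random((7, 12))
    _, recon = refit_autoencoder(X, AutoencoderSpec(**FAST_SPEC))
    assert recon.shape == X.shape


def test_bottleneck_must_compress():
    with pytest.raises(ValueError, match="bottleneck"):
        AutoencoderSpec(encoder_widths=(8, 5)).resolve_widths(4)


# -- full decomposition ------------------------------------------------------

def test_noiseless_clean_matrix_is_fixed_point(two_clone_block):
    # 20 cells fit in one batch; more epochs make up for fewer steps/epoch
    X, _ = two_clone_block
    res = decompose(
        X, np.ones_like(X), RDAConfig(), AutoencoderSpec(inner_epochs=60, seed=3)
    )
    assert np.array_equal(res.genotype_calls, X.astype(np.int8))
    assert np.count_nonzero(res.S) == 0


def test_masked_entries_imputed(two_clone_block):
    """30% of a clean two-clone matrix hidden: imputation restores >= 95%."""
    X, _ = two_clone_block
    hits, total = 0, 0
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        mask = (rng.random(X.shape) >= 0.3).astype(float)
        res = decompose(
            X * mask, mask, RDAConfig(), AutoencoderSpec(inner_epochs=60, seed=seed)
        )
        hidden = mask == 0
        hits += int((res.genotype_calls[hidden] == X[hidden]).sum())
        total += int(hidden.sum())
    assert hits / total >= 0.95


def test_trace_contract_on_convergence(two_clone_block):
    X, _ = two_clone_block
    cfg = RDAConfig(epsilon=0.5)  # loose tolerance forces early convergence
    res = decompose(X, np.ones_like(X), cfg, AutoencoderSpec(**FAST_SPEC))
    assert res.trace
    if res.converged:
        c1, c2 = res.trace[-1]
        assert min(c1, c2) < cfg.epsilon


def test_unobserved_constraint_conservation(two_clone_block):
    """LD + S = X holds exactly outside omega after every outer sweep."""
    X, _ = two_clone_block
    rng = np.random.default_rng(7)
    mask = (rng.random(X.shape) >= 0.25).astype(float)
    Xm = X * mask
    for iters in (1, 2, 4):
        res = decompose(
            Xm, mask, RDAConfig(max_outer_iters=iters),
            AutoencoderSpec(**FAST_SPEC),
        )
        outside = mask == 0
        assert np.array_equal(
            (res.LD + res.S)[outside], Xm[outside]
        ), f"violated after {iters} iterations"


def test_sparsity_monotone_in_lambda(two_clone_block):
    X, _ = two_clone_block
    rng = np.random.default_rng(5)
    noisy = np.abs(X - (rng.random(X.shape) < 0.15))  # flip 15%
    mask = np.ones_like(X)
    nnz = []
    for lam in (0.01, 0.05, 0.1, 0.5):
        res = decompose(
            noisy, mask, RDAConfig(lam=lam), AutoencoderSpec(**FAST_SPEC)
        )
        nnz.append(np.count_nonzero(res.S * mask))
    assert nnz == sorted(nnz, reverse=True)


def test_decompose_deterministic(two_clone_block):
    X, _ = two_clone_block
    runs = [
        decompose(X, np.ones_like(X), RDAConfig(), AutoencoderSpec(**FAST_SPEC))
        for _ in range(2)
    ]
    assert runs[0].trace == runs[1].trace
    assert np.array_equal(runs[0].genotype_calls, runs[1].genotype_calls)
    assert np.array_equal(runs[0].LD, runs[1].LD)


def test_zero_matrix_rejected():
    with pytest.raises(DegenerateInputError):
        decompose(np.zeros((4, 3)), np.ones((4, 3)))


def test_residual_normalisation_is_scale_free(rng):
    """Scaling (X, LD, lambda) together leaves c1/c2-style residuals unchanged.

    This checks the normalised-residual machinery around the autoencoder
    step: the S update, the shrink and the ||.||/||X|| normalisation are
    jointly scale-equivariant.
    """
    X = rng.random((6, 5))
    LD = rng.random((6, 5))
    mask = (rng.random((6, 5)) > 0.3).astype(float)
    lam = 0.2

    def residuals(X, LD, lam):
        S = shrink(X - LD, lam, mask)
        c1 = np.linalg.norm(X - LD - S) / np.linalg.norm(X)
        c2 = np.linalg.norm((LD + S) - X) / np.linalg.norm(X)
        return c1, c2

    base = residuals(X, LD, lam)
    for c in (0.5, 3.0):
        scaled = residuals(c * X, c * LD, c * lam)
        assert scaled == pytest.approx(base, rel=1e-12)
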