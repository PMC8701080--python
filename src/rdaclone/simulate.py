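"""Ground-truthed synthetic single-cell SNV datasets.

The generative process mirrors the two-step design used to benchmark
genotype-matrix recovery tools: first a random clonal tree over K subclones
(uniform attachment: each new clone picks its parent uniformly among
existing clones; clone 0 is the unmutated normal root), with every genotype
site placed on exactly one tree edge under an infinite-sites model (no back
mutation, each non-root clone gains at least one private site).  A clone's
genotype is the union of mutations along its root path, so genotypes are
monotone — child ⊇ parent.

Cells are then assigned to clones (a guaranteed minimum per clone plus a
uniform multinomial remainder) and the clean matrix is corrupted
independently per entry: a true 0 flips to 1 with probability FPR
(amplification artifact), a true 1 flips to 0 with probability FNR (allelic
dropout), and afterwards each entry is erased to missing with probability
MR — missingness is applied after the flips so that the three rates stay
independent, as a factorial sweep design assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, ObservedGenotypeMatrix


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    fpr: float = 0.15
    fnr: float = 0.15
    mr: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.fpr < 1 and 0 <= self.fnr < 1 and 0 <= self.mr <= 1):
            raise SimulationConfigError(
                "fpr/fnr must lie in [0,1), mr in [0,1]"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of one simulated dataset.

    Defaults match the fixed operating point of the benchmark sweeps
    (FPR = FNR = 0.15, MR = 0.3) at desk scale.
    """

    n_cells: int = 300
    n_sites: int = 200
    n_subclones: int = 10
    fpr: float = 0.15
    fnr: float = 0.15
    mr: float = 0.3
    seed: int = 0
    min_cells_per_clone: int = 3

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_sites < 1 or self.n_subclones < 1:
            raise SimulationConfigError("n_cells, n_sites, n_subclones invalid")
        if self.min_cells_per_clone < 1:
            raise SimulationConfigError("min_cells_per_clone must be >= 1")
        if self.n_subclones * self.min_cells_per_clone > self.n_cells:
            raise SimulationConfigError(
                f"{self.n_subclones} subclones x {self.min_cells_per_clone} "
                f"min cells exceed {self.n_cells} cells"
            )
        if self.n_subclones > self.n_sites + 1:
            raise SimulationConfigError(
                "each non-root subclone needs at least one private site: "
                f"{self.n_subclones} subclones > {self.n_sites} sites + 1"
            )
        NoiseModel(self.fpr, self.fnr, self.mr)  # validates ranges

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.fpr, self.fnr, self.mr)


@dataclass
class SimulatedDataset:
    truth_matrix: np.ndarray            # n×m in {0,1}
    observed: ObservedGenotypeMatrix
    true_labels: np.ndarray             # per-cell subclone index
    true_tree: np.ndarray               # parent array; parent[0] = -1
    clone_genotypes: np.ndarray         # K×m in {0,1}
    config: SimulationConfig = field(repr=False)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *stream])


def simulate_clone_tree(
    n_subclones: int, n_sites: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-attachment clone tree and infinite-sites genotype assignment.

    Returns (parent array with parent[0] = -1, K×m clone genotype matrix).
    Each site mutates on exactly one edge; every non-root clone receives at
    least one private site.
    """
    if n_subclones > n_sites + 1:
        raise SimulationConfigError(
            f"{n_subclones} subclones need at least {n_subclones - 1} sites"
        )
    rng = _rng(seed, 0x7E)
    parent = np.full(n_subclones, -1, dtype=np.int64)
    for k in range(1, n_subclones):
        parent[k] = rng.integers(0, k)

    genotypes = np.zeros((n_subclones, n_sites), dtype=np.int8)
    if n_subclones > 1:
        # edge of clone k = (parent[k], k); guarantee one site per edge,
        # spread the rest uniformly
        site_owner = np.empty(n_sites, dtype=np.int64)
        guaranteed = rng.choice(n_sites, size=n_subclones - 1, replace=False)
        site_owner[guaranteed] = np.arange(1, n_subclones)
        rest = np.setdiff1d(np.arange(n_sites), guaranteed)
        site_owner[rest] = rng.integers(1, n_subclones, size=len(rest))
        for k in range(1, n_subclones):
            genotypes[k] = genotypes[parent[k]].copy()
            genotypes[k, site_owner == k] = 1
    return parent, genotypes


def assign_cells(
    n_cells: int,
    n_subclones: int,
    min_cells_per_clone: int,
    seed: int,
) -> np.ndarray:
    """Per-cell clone labels: a floor per clone, then a uniform multinomial."""
    if n_subclones * min_cells_per_clone > n_cells:
        raise SimulationConfigError("not enough cells for the per-clone floor")
    rng = _rng(seed, 0xCE)
    counts = np.full(n_subclones, min_cells_per_clone, dtype=np.int64)
    remainder = n_cells - counts.sum()
    counts += rng.multinomial(remainder, np.full(n_subclones, 1 / n_subclones))
    labels = np.repeat(np.arange(n_subclones), counts)
    rng.shuffle(labels)
    return labels


def apply_noise(
    truth: np.ndarray, noise: NoiseModel, seed: int
) -> ObservedGenotypeMatrix:
    """Corrupt a clean binary matrix with FP/FN flips, then erase to missing."""
    truth = np.asarray(truth)
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth matrix must be binary")
    rng = _rng(seed, 0xF1)
    u_flip = rng.random(truth.shape)
    flip_p = np.where(truth == 0, noise.fpr, noise.fnr)
    observed = np.where(u_flip < flip_p, 1 - truth, truth).astype(np.int8)
    u_miss = rng.random(truth.shape)
    observed[u_miss < noise.mr] = MISSING
    return ObservedGenotypeMatrix(values=observed)


def degrade_missing(
    g: ObservedGenotypeMatrix, target_mr: float, seed: int
) -> tuple[ObservedGenotypeMatrix, np.ndarray]:
    """Raise the missing fraction to target_mr by masking random observed entries.

    Returns the degraded matrix and the (row, col) array of newly masked
    entries, which downstream imputation accuracy is scored on.
    """
    current = g.missing_rate
    if target_mr < current - 1e-12:
        raise ValueError(
            f"target missing rate {target_mr:.4f} is below the current "
            f"{current:.4f}"
        )
    total = g.n * g.m
    n_target = int(round(target_mr * total))
    n_new = n_target - int((g.values == MISSING).sum())
    observed_idx = np.argwhere(g.values != MISSING)
    if n_new <= 0:
        return (
            ObservedGenotypeMatrix(
                values=g.values.copy(),
                cell_ids=list(g.cell_ids),
                site_ids=list(g.site_ids),
            ),
            np.empty((0, 2), dtype=np.int64),
        )
    rng = _rng(seed, 0xD6)
    chosen = observed_idx[
        rng.choice(len(observed_idx), size=n_new, replace=False)
    ]
    values = g.values.copy()
    values[chosen[:, 0], chosen[:, 1]] = MISSING
    return (
        ObservedGenotypeMatrix(
            values=values, cell_ids=list(g.cell_ids), site_ids=list(g.site_ids)
        ),
        chosen,
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Compose tree → cell assignment → clean matrix → noise into one bundle."""
    parent, clone_gt = simulate_clone_tree(
        cfg.n_subclones, cfg.n_sites, cfg.seed
    )
    labels = assign_cells(
        cfg.n_cells, cfg.n_subclones, cfg.min_cells_per_clone, cfg.seed
    )
    truth = clone_gt[labels]
    observed = apply_noise(truth, cfg.noise, cfg.seed)
    return SimulatedDataset(
        truth_matrix=truth.astype(np.int8),
        observed=observed,
        true_labels=labels,
        true_tree=parent,
        clone_genotypes=clone_gt,
        config=cfg,
    )
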