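"""FRECL: K-means-type functional regression clustering, with consensus.

A single run alternates between (a) fitting one function-on-function
regression model per non-empty cluster and (b) reassigning every
observation to the model with the smallest residual norm. Clusters may
empty out during a run and never return, so the number of active clusters
is non-increasing. A run converges when two consecutive partitions are
identical; exact partition repeats (cycles) are detected by hashing and
stop the run unconverged.

Because a run's outcome depends on its random initial partition, the
complete procedure performs L independent runs, discards the
non-convergent ones, accumulates binary co-assignment matrices into a
consensus matrix B, and K-means-clusters the rows of B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .fofr import BasisSpec, FoFModel, fit_fofr, residual_norms_many
from .functional import FRDataset

logger = logging.getLogger("frecl")

__all__ = [
    "Partition",
    "FreclConfig",
    "RunResult",
    "ConsensusMatrix",
    "random_partition",
    "reassign_step",
    "frecl_run",
    "consensus_matrix",
    "consensus_cluster",
    "frecl_consensus",
    "fit_partition_models",
    "mse_profile",
    "select_k_elbow",
]


@dataclass
class Partition:
    """Assignment of m observations to at most K clusters.

    Labels are integers in 1..K; empty clusters are permitted. ``ids``
    carries the observation identifiers in label order.
    """

    labels: np.ndarray
    K: int
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d integer vector")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.K):
            raise ValueError("labels must lie in 1..K")
        if self.ids is not None and len(self.ids) != self.labels.size:
            raise ValueError("ids must match labels in length")

    @property
    def m(self) -> int:
        return self.labels.size

    def cluster_ids(self) -> np.ndarray:
        """Sorted labels of the non-empty clusters."""
        return np.unique(self.labels)

    @property
    def n_clusters(self) -> int:
        """Number of non-empty clusters."""
        return self.cluster_ids().size

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def compact(self) -> "Partition":
        """Relabel non-empty clusters to 1..K' preserving label order."""
        ids = self.cluster_ids()
        mapping = {int(old): new for new, old in enumerate(ids, start=1)}
        new_labels = np.array([mapping[int(l)] for l in self.labels])
        return Partition(new_labels, K=ids.size, ids=self.ids)


@dataclass(frozen=True)
class FreclConfig:
    """Settings for a complete FRECL analysis.

    Parameters
    ----------
    K
        Requested number of clusters (> 1).
    norm
        Residual norm used for reassignment: 2 (default) or 1.
    max_iter
        Iteration cap per run (default 300).
    L
        Number of runs aggregated by consensus (default 30; consensus
        is typically stable from 20-30 runs on).
    seed
        Master seed; every run and the consensus K-means derive their
        randomness from it.
    basis
        Basis/penalty settings handed to the per-cluster fits.
    """

    K: int = 3
    norm: int = 2
    max_iter: int = 300
    L: int = 30
    seed: int = 0
    basis: BasisSpec = field(default_factory=BasisSpec)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be > 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.norm not in (1, 2):
            raise ValueError("norm must be 1 (L1) or 2 (L2)")


@dataclass
class RunResult:
    """Outcome of one FRECL run."""

    partition: Partition
    models: list[FoFModel]
    n_iter: int
    converged: bool
    cycle: bool = False
    trace: list[Partition] | None = None
    log: list[dict] = field(default_factory=list)


@dataclass
class ConsensusMatrix:
    """Aggregated co-assignment counts over the convergent runs."""

    B: np.ndarray
    L_effective: int
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        B = np.asarray(self.B)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("consensus matrix must be square")
        if not np.array_equal(B, B.T):
            raise ValueError("consensus matrix must be symmetric")
        if B.min() < 0 or B.max() > self.L_effective:
            raise ValueError("entries must lie in 0..L_effective")
        self.B = B


# ---------------------------------------------------------------------------
# single run


def random_partition(m: int, K: int, rng: np.random.Generator,
                     ids: list[str] | None = None) -> Partition:
    """Uniform random partition of m observations with K non-empty clusters.

    One observation per cluster is seeded (guaranteeing non-emptiness);
    the remainder are assigned uniformly at random.
    """
    if K < 2:
        raise ValueError("K must be > 1")
    if m < K:
        raise ValueError(f"cannot form {K} non-empty clusters from {m} observations")
    labels = rng.integers(1, K + 1, size=m)
    seeds = rng.choice(m, size=K, replace=False)
    labels[seeds] = np.arange(1, K + 1)
    return Partition(labels, K=K, ids=ids)


def _residual_matrix(dataset: FRDataset, models: Sequence[FoFModel],
                     norm: int) -> np.ndarray:
    """m x K matrix of residual norms r_hat[i, k]."""
    return np.column_stack(
        [residual_norms_many(mod, dataset, norm=norm) for mod in models])


def reassign_step(dataset: FRDataset, models: Sequence[FoFModel],
                  norm: int = 2) -> Partition:
    """Reallocate each observation to its best-fitting model.

    labels[i] = argmin_k r_hat[i, k]; exact ties go to the smallest
    cluster index.
    """
    if not models:
        raise ValueError("reassign_step needs at least one fitted model")
    R = _residual_matrix(dataset, models, norm)
    labels = np.argmin(R, axis=1) + 1  # argmin takes the first minimum
    return Partition(labels, K=len(models), ids=dataset.ids)


def fit_partition_models(dataset: FRDataset, partition: Partition,
                         basis: BasisSpec) -> list[FoFModel]:
    """One model per non-empty cluster, in ascending label order."""
    return [fit_fofr(dataset, basis, indices=partition.members(k))
            for k in partition.cluster_ids()]


def frecl_run(dataset: FRDataset, config: FreclConfig,
              rng: np.random.Generator, keep_trace: bool = False,
              init: Partition | None = None) -> RunResult:
    """One FRECL run from a random (or supplied) initial partition.

    Alternates per-cluster fits with residual-norm reassignment until two
    consecutive partitions coincide, a previously visited partition
    recurs (cycle; unconverged), or ``max_iter`` is reached. After each
    reassignment the working K becomes the number of non-empty clusters.
    A collapse to a single cluster yields a valid (flagged) single-cluster
    result, not an error.
    """
    if init is not None:
        if init.m != dataset.m:
            raise ValueError("initial partition does not match the dataset")
        part = init.compact()
    else:
        part = random_partition(dataset.m, config.K, rng, ids=dataset.ids).compact()
    trace = [part] if keep_trace else None
    seen = {part.labels.tobytes()}
    log: list[dict] = []
    models: list[FoFModel] = []
    converged = False
    cycle = False
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        models = fit_partition_models(dataset, part, config.basis)
        R = _residual_matrix(dataset, models, config.norm)
        labels = np.argmin(R, axis=1) + 1
        new = Partition(labels, K=len(models), ids=dataset.ids).compact()
        log.append({
            "iteration": n_iter,
            "cluster_sizes": list(new.sizes().values()),
            "total_sq_residual": float(np.sum(R[np.arange(dataset.m),
                                                labels - 1] ** 2)),
        })
        if keep_trace:
            trace.append(new)
        if np.array_equal(new.labels, part.labels):
            part = new
            converged = True
            break
        key = new.labels.tobytes()
        if key in seen:
            part = new
            cycle = True
            logger.warning("run entered a partition cycle at iteration %d", n_iter)
            break
        seen.add(key)
        part = new

    if converged and part.n_clusters != len(models):
        # converged partition may have fewer clusters than fitted models
        models = [mod for k, mod in enumerate(models, start=1)
                  if np.any(part.labels == k)]
    if part.n_clusters == 1:
        logger.warning("run collapsed to a single cluster")
    # models must match the returned partition's non-empty clusters
    if len(models) != part.n_clusters:
        models = fit_partition_models(dataset, part, config.basis)
    return RunResult(part, models, n_iter, converged, cycle, trace, log)


# ---------------------------------------------------------------------------
# consensus


def consensus_matrix(partitions: Sequence[Partition]) -> ConsensusMatrix:
    """B = sum_l A(l) with A(l)_ij = 1 iff i and j share a cluster in P_l."""
    if not partitions:
        raise ValueError("no partitions to aggregate")
    m = partitions[0].m
    B = np.zeros((m, m), dtype=int)
    for part in partitions:
        if part.m != m:
            raise ValueError("partitions must cover the same observations")
        A = (part.labels[:, None] == part.labels[None, :])
        B += A
    return ConsensusMatrix(B, L_effective=len(partitions),
                           ids=partitions[0].ids)


def consensus_cluster(partitions: Sequence[Partition], K: int,
                      rng: np.random.Generator) -> Partition:
    """K-means (k-means++, 10 restarts) on the rows of the consensus matrix.

    Raises
    ------
    ValueError
        If no partitions (convergent runs) are supplied.
    """
    if not partitions:
        raise ValueError("consensus requires at least one convergent run")
    cm = consensus_matrix(partitions)
    seed = int(rng.integers(2**31 - 1))
    km = KMeans(n_clusters=min(K, cm.B.shape[0]), init="k-means++",
                n_init=10, random_state=seed)
    labels = km.fit_predict(cm.B.astype(float)) + 1
    return Partition(labels, K=K, ids=cm.ids).compact()


def frecl_consensus(dataset: FRDataset, config: FreclConfig,
                    ) -> tuple[Partition, ConsensusMatrix, list[RunResult]]:
    """Complete FRECL: L seeded runs, then consensus over the convergent ones.

    Run seeds derive deterministically from ``config.seed``; a fixed seed
    yields a bitwise-identical consensus partition. If *no* run converges,
    the final partitions of the unconverged runs are used instead, with a
    prominent warning (discarding everything would leave no answer).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.L + 1)
    runs = [frecl_run(dataset, config, np.random.default_rng(children[l]))
            for l in range(config.L)]
    convergent = [r for r in runs if r.converged]
    if not convergent:
        warnings.warn("no FRECL run converged within max_iter; falling back "
                      "to the final partitions of all runs", stacklevel=2)
        convergent = runs
    logger.info("consensus over %d/%d convergent runs", len(convergent), len(runs))
    cm = consensus_matrix([r.partition for r in convergent])
    part = consensus_cluster([r.partition for r in convergent], config.K,
                             np.random.default_rng(children[config.L]))
    return part, cm, runs


# ---------------------------------------------------------------------------
# model selection


def mse_profile(dataset: FRDataset, K_values: Sequence[int],
                config: FreclConfig) -> list[tuple[int, float]]:
    """MSE(K) = (1/m) sum_k sum_{i in C_k} r_hat_ik^2 over a range of K.

    For each K a full consensus clustering is performed, the models are
    refitted once on the consensus partition, and the mean squared
    residual norm of each observation under its assigned cluster's model
    is reported.
    """
    out = []
    for K in K_values:
        if not 2 <= K <= dataset.m:
            raise ValueError(f"K={K} outside 2..m")
        part, _, _ = frecl_consensus(dataset, replace(config, K=K))
        models = fit_partition_models(dataset, part, config.basis)
        R = _residual_matrix(dataset, models, config.norm)
        compact = part.compact()
        r_assigned = R[np.arange(dataset.m), compact.labels - 1]
        out.append((K, float(np.mean(r_assigned**2))))
    return out


def select_k_elbow(profile: Sequence[tuple[int, float]]) -> int:
    """Elbow choice of K: the interior K maximizing the discrete second
    difference MSE(K-1) - 2 MSE(K) + MSE(K+1).

    A flat or strictly linear profile has no elbow; the smallest interior
    K is returned with a warning.
    """
    if len(profile) < 3:
        raise ValueError("elbow selection needs at least 3 profile points")
    Ks = [k for k, _ in profile]
    if Ks != sorted(Ks):
        raise ValueError("profile must be sorted by ascending K")
    mse = np.array([v for _, v in profile], dtype=float)
    curv = mse[:-2] - 2 * mse[1:-1] + mse[2:]
    if np.allclose(curv, curv[0]):
        warnings.warn("MSE profile has no elbow (constant curvature); "
                      "returning the smallest interior K", stacklevel=2)
        return Ks[1]
    return Ks[1 + int(np.argmax(curv))]
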