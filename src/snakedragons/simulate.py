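"""Controlled-noise simulation of correlation matrices and the
two-class clustering benchmark.

Naively adding noise to a correlation matrix breaks positive
semidefiniteness, so noise is injected through sampling instead: a
prototype matrix serves as the covariance of a multivariate normal, a
``q x n`` data matrix is drawn from it, and its sample correlation
matrix is the noisy replicate.  The smaller ``n`` (the larger ``q/n``),
the noisier the replicate; ``q/n`` is the single noise knob.

The separation between two simulated classes is summarized by a
signal-to-noise ratio: the Euclidean distance between the two classes'
mean snake vectors divided by the root mean squared within-class
deviation (pooled over both classes).

The benchmark simulates two classes from a pair of prototype matrices
over a grid of ``q/n`` values and scores how well each comparison
method (random skewers / T / S1 with hierarchical clustering; snake
vectors with Ward, k-means, and consensus clustering) recovers the
class labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster_engine, matrix_distance
from .evaluate import confusion_and_misclassification
from .matrix_io import CorrelationMatrix, MatrixCollection, synth_labels
from .vectorize import snake

BENCHMARK_METHODS = ("rs", "t", "s1", "snake-ward", "snake-kmeans", "snake-consensus")


class SimulationError(Exception):
    pass


@dataclass
class SnakeEnsemble:
    """Snake vectors of the simulated matrices of one class."""

    class_tag: str
    snakes: np.ndarray  # m x L

    @property
    def centroid(self) -> np.ndarray:
        return self.snakes.mean(axis=0)


@dataclass
class SimulationDesign:
    prototype_a: CorrelationMatrix
    prototype_b: CorrelationMatrix
    q_over_n_grid: list[float] = field(default_factory=lambda: [0.1, 2, 3, 4, 6, 9, 12])
    m_per_class: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.prototype_a.q != self.prototype_b.q:
            raise SimulationError("prototypes must share q")
        if any(r <= 0 for r in self.q_over_n_grid):
            raise SimulationError("q/n values must be positive")

    @property
    def q(self) -> int:
        return self.prototype_a.q

    def n_for(self, q_over_n: float) -> int:
        return n_from_ratio(self.q, q_over_n)


def n_from_ratio(q: int, q_over_n: float) -> int:
    """Sample count for a target q/n ratio (nearest integer, >= 2)."""
    return max(2, round(q / q_over_n))


def _psd_factor(prototype: CorrelationMatrix) -> np.ndarray:
    """Square-root factor of the prototype, clipping tiny negative
    eigenvalues (tolerated down to -1e-6) and renormalizing to unit
    diagonal if clipping was needed."""
    V = (prototype.values + prototype.values.T) / 2.0
    lam, E = np.linalg.eigh(V)
    if lam[0] < -1e-6:
        raise SimulationError(
            f"prototype is not PSD (smallest eigenvalue {lam[0]:.3g})"
        )
    if lam[0] < 0:
        lam = np.clip(lam, 0.0, None)
        V = E @ np.diag(lam) @ E.T
        d = np.sqrt(np.diag(V))
        V = V / np.outer(d, d)
        lam, E = np.linalg.eigh(V)
        lam = np.clip(lam, 0.0, None)
    return E * np.sqrt(lam)


def simulate_noisy_correlation(
    prototype: CorrelationMatrix,
    n: int,
    rng: int | np.random.Generator = 0,
    name: str | None = None,
) -> CorrelationMatrix:
    """Sample correlation matrix of n multivariate-normal draws with the
    prototype as covariance.

    Larger n gives replicates closer to the prototype.  When ``n < q``
    the sample correlation matrix is rank-deficient — expected and legal
    (the noisiest benchmark settings use n as small as 3 with q = 36).
    """
    if n < 2:
        raise SimulationError("need n >= 2 draws")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    F = _psd_factor(prototype)
    q = prototype.q
    X = F @ rng.standard_normal((q, n))
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(list(prototype.labels), C, name=name)


def element_sd_profile(
    prototype: CorrelationMatrix,
    n: int,
    n_replicates: int = 200,
    rng: int | np.random.Generator = 0,
    bin_edges: np.ndarray | None = None,
):
    """Across-replicate SD of each off-diagonal element, plus a
    fixed-bin histogram of those SDs (for noise-level profiling)."""
    if n_replicates < 2:
        raise SimulationError("need at least 2 replicates")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    q = prototype.q
    iu = np.triu_indices(q, 1)
    reps = np.stack(
        [simulate_noisy_correlation(prototype, n, rng).values[iu] for _ in range(n_replicates)]
    )
    sds = reps.std(axis=0, ddof=1)
    edges = bin_edges if bin_edges is not None else np.linspace(0.0, 1.0, 51)
    hist, _ = np.histogram(sds, bins=edges)
    return {
        "sds": sds,
        "mean_sd": float(sds.mean()),
        "hist": hist,
        "bin_edges": edges,
        "n": n,
        "n_replicates": n_replicates,
    }


def snr(ensemble_a: SnakeEnsemble | np.ndarray, ensemble_b: SnakeEnsemble | np.ndarray) -> float:
    """Signal-to-noise ratio between two snake ensembles.

    Numerator: Euclidean distance between the class centroids.
    Denominator: square root of the pooled mean squared within-class
    deviation, ``sqrt((SS_a + SS_b) / (M_a + M_b))``.  Identical
    centroids give 0; zero within-class spread gives +inf with a
    warning.
    """
    A = ensemble_a.snakes if isinstance(ensemble_a, SnakeEnsemble) else np.asarray(ensemble_a, dtype=float)
    B = ensemble_b.snakes if isinstance(ensemble_b, SnakeEnsemble) else np.asarray(ensemble_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise SimulationError("snake lengths differ between ensembles")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise SimulationError("each ensemble needs at least 2 snakes")
    abar, bbar = A.mean(axis=0), B.mean(axis=0)
    signal = float(np.linalg.norm(abar - bbar))
    ss = float(np.sum((A - abar) ** 2) + np.sum((B - bbar) ** 2))
    denom = np.sqrt(ss / (A.shape[0] + B.shape[0]))
    if denom == 0.0:
        warnings.warn("zero within-class spread; SNR is +inf")
        return float("inf")
    return signal / denom


def _block_prototype(
    q: int,
    n_blocks: int,
    within_range: tuple[float, float],
    rng: np.random.Generator,
    offset: int = 0,
) -> CorrelationMatrix:
    """Unit-diagonal block-factor correlation matrix: node i carries a
    loading sqrt(rho_i) on its block's factor, so within-block
    correlations are sqrt(rho_i rho_j), between-block zero; PSD by
    construction.  ``offset`` rotates the node-to-block assignment so
    that two prototypes' block boundaries can be misaligned."""
    sizes = [q // n_blocks + (1 if b < q % n_blocks else 0) for b in range(n_blocks)]
    loadings = np.zeros((q, n_blocks))
    order = np.roll(np.arange(q), offset)
    node = 0
    for b, size in enumerate(sizes):
        rho = rng.uniform(*within_range, size=size)
        loadings[order[node : node + size], b] = np.sqrt(rho)
        node += size
    V = loadings @ loadings.T
    np.fill_diagonal(V, 1.0)
    return CorrelationMatrix(synth_labels(q), V)


def _dense_background(q: int, rng: np.random.Generator) -> np.ndarray:
    """Full-rank Wishart-type correlation matrix: the diffuse structure
    a real system's matrices share regardless of class."""
    G = rng.standard_normal((q, q)) / np.sqrt(q)
    W = G @ G.T
    d = np.sqrt(np.diag(W))
    W = W / np.outer(d, d)
    np.fill_diagonal(W, 1.0)
    return W


def generate_prototype_pair(
    q: int = 36,
    blocks_a: int = 4,
    blocks_b: int = 2,
    within_range: tuple[float, float] = (0.7, 0.95),
    offset_b: int = 4,
    structure_weight: float = 0.8,
    target_snr_floor: float | None = None,
    reference_q_over_n: float = 4.0,
    m_pilot: int = 10,
    max_attempts: int = 20,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[CorrelationMatrix, CorrelationMatrix, dict]:
    """Two distinct PSD prototype correlation matrices with tunable
    separation (synthetic stand-ins for a pair of observed matrices
    representing two classes).

    Each prototype is a convex combination
    ``structure_weight * block structure + (1 - structure_weight) *
    shared dense background``: the block structures differ between the
    classes (four communities versus two, the second rotated by
    ``offset_b`` nodes so the layouts are misaligned rather than
    nested), while the full-rank background is common to both — like
    two classes of connectivity matrices that share an organ's diffuse
    correlation structure but differ in community organization.  The
    combination of two unit-diagonal PSD matrices is itself a valid
    correlation matrix, so no repair is needed.

    When ``target_snr_floor`` is given, a pilot simulation at
    ``reference_q_over_n`` checks the snake-ensemble SNR of the pair
    and regenerates (up to ``max_attempts``) until the floor is met.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if not 0 < structure_weight <= 1:
        raise SimulationError("structure_weight must be in (0, 1]")
    n_ref = n_from_ratio(q, reference_q_over_n)
    for attempt in range(max_attempts):
        bg = _dense_background(q, rng)
        A_blocks = _block_prototype(q, blocks_a, within_range, rng)
        B_blocks = _block_prototype(q, blocks_b, within_range, rng, offset=offset_b)
        w = structure_weight
        A = CorrelationMatrix(
            synth_labels(q), w * A_blocks.values + (1 - w) * bg
        )
        B = CorrelationMatrix(
            synth_labels(q), w * B_blocks.values + (1 - w) * bg
        )
        if np.allclose(A.values, B.values):
            continue  # zero separation; reject
        meta = {"attempt": attempt + 1, "q": q, "blocks": (blocks_a, blocks_b)}
        if target_snr_floor is None:
            return A, B, meta
        ens_a = np.stack(
            [snake(simulate_noisy_correlation(A, n_ref, rng)).values for _ in range(m_pilot)]
        )
        ens_b = np.stack(
            [snake(simulate_noisy_correlation(B, n_ref, rng)).values for _ in range(m_pilot)]
        )
        pilot = snr(ens_a, ens_b)
        if pilot >= target_snr_floor:
            meta.update(
                pilot_snr=pilot,
                reference_q_over_n=reference_q_over_n,
                target_snr_floor=target_snr_floor,
            )
            return A, B, meta
    raise SimulationError(
        f"could not reach SNR floor {target_snr_floor} in {max_attempts} attempts"
    )


def simulate_two_class_collection(
    design: SimulationDesign, q_over_n: float, rng: np.random.Generator
) -> tuple[MatrixCollection, np.ndarray]:
    """2m simulated matrices (m per prototype) at one grid point, with
    true class labels (1 = class a, 2 = class b)."""
    n = design.n_for(q_over_n)
    m = design.m_per_class
    mats, ids = [], []
    for tag, proto in (("a", design.prototype_a), ("b", design.prototype_b)):
        for i in range(m):
            mats.append(
                simulate_noisy_correlation(proto, n, rng, name=f"{tag}{i + 1:03d}")
            )
            ids.append(f"{tag}{i + 1:03d}")
    truth = np.array([1] * m + [2] * m)
    return MatrixCollection(ids, mats), truth


def run_two_class_benchmark(
    design: SimulationDesign,
    methods=BENCHMARK_METHODS,
    rng_seed: int | None = None,
    n_skewers: int = 100,
    consensus_resamples: int = 200,
    consensus_restarts: int = 10,
) -> pd.DataFrame:
    """Misclassification error of each method across the q/n grid.

    Per grid point: simulate m matrices per class, record the SNR of
    the two snake ensembles, cluster all 2m objects into k = 2 with
    each requested method, and score the permutation-minimized
    misclassification against the true classes.  Returns a tidy table
    (q_over_n, n, snr, method, error, cell_seed); failures are recorded
    as NaN error rather than aborting the run.
    """
    seed = design.rng_seed if rng_seed is None else rng_seed
    unknown = set(methods) - set(BENCHMARK_METHODS)
    if unknown:
        raise SimulationError(f"unknown methods {sorted(unknown)}")
    rows = []
    for gi, q_over_n in enumerate(design.q_over_n_grid):
        cell_seed = [int(seed), gi]
        rng = np.random.default_rng(cell_seed)
        collection, truth = simulate_two_class_collection(design, q_over_n, rng)
        X = np.stack([snake(m).values for m in collection.matrices])
        m = design.m_per_class
        cell_snr = snr(X[:m], X[m:])
        n = design.n_for(q_over_n)
        for method in methods:
            try:
                labels = _cluster_cell(
                    method,
                    collection,
                    X,
                    seed=int(rng.integers(2**31)),
                    n_skewers=n_skewers,
                    consensus_resamples=consensus_resamples,
                    consensus_restarts=consensus_restarts,
                )
                _, error = confusion_and_misclassification(truth, labels)
            except Exception as exc:  # record, don't abort the grid
                warnings.warn(f"cell q/n={q_over_n}, {method}: {exc}")
                error = float("nan")
            rows.append(
                {
                    "q_over_n": q_over_n,
                    "n": n,
                    "snr": cell_snr,
                    "method": method,
                    "error": error,
                    "cell_seed": str(cell_seed),
                }
            )
    return pd.DataFrame(rows)


def _cluster_cell(
    method: str,
    collection: MatrixCollection,
    X: np.ndarray,
    seed: int,
    n_skewers: int,
    consensus_resamples: int,
    consensus_restarts: int,
) -> np.ndarray:
    if method in ("rs", "t", "s1"):
        tag = {"rs": "random-skewers", "t": "t-statistic", "s1": "s1"}[method]
        D = matrix_distance.pairwise(collection, tag, n_skewers=n_skewers, rng_seed=seed)
        labels, _ = cluster_engine.hierarchical_partition(distances=D, k=2)
        return labels
    if method == "snake-ward":
        labels, _ = cluster_engine.hierarchical_partition(vectors=X, k=2)
        return labels
    if method == "snake-kmeans":
        return cluster_engine.kmeans_partition(X, 2, rng_seed=seed)
    if method == "snake-consensus":
        _, result = cluster_engine.consensus_cluster(
            X,
            k_range=[2],
            n_resamples=consensus_resamples,
            rng_seed=seed,
            n_restarts=consensus_restarts,
        )
        return result.labels_by_k[2]
    raise SimulationError(f"unknown method {method!r}")
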