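"""Snake and dragon vectorization of correlation matrices.

A *snake* vector lays out the q(q-1)/2 off-diagonal correlations of one
matrix along a serpentine path, turning the structure of a system into
an ordinary feature vector that any vector-clustering method can
consume.  A *dragon* vector concatenates a snake with further named
blocks — variable means/variances (dragon 1), whole-network summary
statistics (dragon 2), snakes from several sites or dimensions
(dragon 3), or arbitrary mixed blocks (dragon 4).

The canonical serpentine ordering walks the superdiagonal bands
k = 1..q-1, traversing odd bands top-to-bottom and even bands
bottom-to-top.  For repeated-measures matrices the k-th band collects
correlations between measurements k steps apart, so this ordering keeps
an interpretable lag structure; a plain row-major upper-triangle
ordering is available too, and any fixed ordering applied consistently
across a collection yields identical distance geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from .matrix_io import CorrelationMatrix, MatrixCollection, synth_labels

ORDERINGS = ("offdiagonal-serpentine", "rowwise-upper")


class VectorizeError(Exception):
    pass


class AssemblyError(VectorizeError):
    pass


class ScalingError(VectorizeError):
    pass


def snake_length(q: int) -> int:
    return q * (q - 1) // 2


def serpentine_indices(q: int, ordering: str = "offdiagonal-serpentine") -> list[tuple[int, int]]:
    """Index pairs (i, j), i<j, in snake order; each unordered pair once."""
    if ordering == "rowwise-upper":
        return [(i, j) for i in range(q) for j in range(i + 1, q)]
    if ordering != "offdiagonal-serpentine":
        raise VectorizeError(f"unknown ordering {ordering!r}")
    pairs: list[tuple[int, int]] = []
    for k in range(1, q):
        band = [(i, i + k) for i in range(q - k)]
        if k % 2 == 0:
            band.reverse()
        pairs.extend(band)
    return pairs


@dataclass
class SnakeVector:
    object_id: str | None
    values: np.ndarray
    ordering_tag: str = "offdiagonal-serpentine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def segment_spans(self) -> dict[str, slice]:
        return {"snake": slice(0, len(self.values))}

    @property
    def segment_roles(self) -> dict[str, str]:
        return {"snake": "snake"}


@dataclass
class DragonVector:
    """Concatenation of named, role-tagged blocks for one object."""

    object_id: str | None
    segments: list[tuple[str, str, np.ndarray]]  # (name, role, values)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([v for _, _, v in self.segments])

    @property
    def segment_spans(self) -> dict[str, slice]:
        spans, start = {}, 0
        for name, _, v in self.segments:
            spans[name] = slice(start, start + len(v))
            start += len(v)
        return spans

    @property
    def segment_roles(self) -> dict[str, str]:
        return {name: role for name, role, _ in self.segments}


@dataclass
class DragonRecipe:
    """Fully determines dragon segment order.

    ``type_tag`` is one of ``dragon1``..``dragon4``.  ``sites`` orders
    the per-site snakes of a dragon 3; ``blocks`` orders the named
    blocks of a dragon 4.  ``threshold`` is the absolute-correlation
    edge threshold used by dragon 2's network summaries.
    """

    type_tag: str
    sites: list[str] | None = None
    blocks: list[str] | None = None
    ordering: str = "offdiagonal-serpentine"
    threshold: float = 0.25


@dataclass
class NetworkSummary:
    mean_connectivity: float
    hub_count: int
    characteristic_path_length: float
    mean_first_neighbors: float
    threshold: float
    connected_pair_fraction: float

    FIELD_ORDER = (
        "mean_connectivity",
        "hub_count",
        "characteristic_path_length",
        "mean_first_neighbors",
    )

    def as_vector(self) -> np.ndarray:
        cpl = self.characteristic_path_length
        return np.array(
            [
                self.mean_connectivity,
                float(self.hub_count),
                cpl if np.isfinite(cpl) else 0.0,
                self.mean_first_neighbors,
            ]
        )


def snake(
    M: CorrelationMatrix,
    ordering: str = "offdiagonal-serpentine",
    object_id: str | None = None,
) -> SnakeVector:
    """Extract the off-diagonal terms of ``M`` along a serpentine path."""
    if M.q < 2:
        raise VectorizeError("snake requires q >= 2")
    pairs = serpentine_indices(M.q, ordering)
    vals = np.array([M.values[i, j] for i, j in pairs])
    return SnakeVector(object_id or M.name, vals, ordering)


def unsnake(
    v: SnakeVector | np.ndarray,
    q: int,
    ordering: str = "offdiagonal-serpentine",
    labels: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Rebuild the correlation matrix from a snake vector (exact inverse)."""
    values = v.values if isinstance(v, SnakeVector) else np.asarray(v, dtype=float)
    if isinstance(v, SnakeVector):
        ordering = v.ordering_tag
    if len(values) != snake_length(q):
        raise VectorizeError(
            f"snake of length {len(values)} does not match q={q} "
            f"(expected {snake_length(q)})"
        )
    V = np.eye(q)
    for (i, j), val in zip(serpentine_indices(q, ordering), values):
        V[i, j] = V[j, i] = val
    name = v.object_id if isinstance(v, SnakeVector) else None
    return CorrelationMatrix(list(labels) if labels else synth_labels(q), V, name=name)


def snake_collection(
    collection: MatrixCollection, ordering: str = "offdiagonal-serpentine"
) -> tuple[list[str], np.ndarray]:
    """Snake every matrix; returns (object_ids, N x L array)."""
    X = np.stack(
        [snake(m, ordering).values for m in collection.matrices]
    )
    return list(collection.object_ids), X


def matrix_from_data(
    X: np.ndarray, var_names: Sequence[str] | None = None, name: str | None = None
) -> tuple[CorrelationMatrix, np.ndarray, np.ndarray]:
    """Pearson correlation matrix of the rows of a variables x repeats matrix.

    Also returns per-variable means and unbiased (n-1) variances across
    the repeated measures — the state descriptors that a dragon 1
    concatenates with the snake.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise VectorizeError("need a 2-D matrix with at least 2 repeated measures")
    variances = X.var(axis=1, ddof=1)
    zero = np.nonzero(variances == 0)[0]
    labels = list(var_names) if var_names else synth_labels(X.shape[0])
    if zero.size:
        raise VectorizeError(
            "zero variance; correlations undefined for variable(s): "
            + ", ".join(labels[i] for i in zero)
        )
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(labels, C, name=name), X.mean(axis=1), variances


def network_summaries(M: CorrelationMatrix, threshold: float = 0.25) -> NetworkSummary:
    """Whole-network descriptors of the thresholded correlation graph.

    An edge joins nodes i, j (i != j) when ``|r_ij| >= threshold``.
    ``mean_connectivity`` ignores the threshold (mean off-diagonal |r|);
    the characteristic path length averages shortest paths over
    connected pairs only, and is NaN when no pair is connected.  Hubs
    are nodes whose degree exceeds mean degree + 2 SD of degree.
    """
    if not 0 <= threshold < 1:
        raise VectorizeError("threshold must be in [0, 1)")
    q = M.q
    A = np.abs(M.values.copy())
    np.fill_diagonal(A, 0.0)
    mean_conn = float(A[np.triu_indices(q, 1)].mean()) if q > 1 else 0.0
    adj = A >= threshold
    degrees = adj.sum(axis=1)
    mean_deg = float(degrees.mean())
    hub_cut = mean_deg + 2.0 * float(degrees.std())  # population SD of the degree sequence
    hubs = int(np.sum(degrees > hub_cut))
    G = nx.from_numpy_array(adj.astype(int))
    total_pairs = q * (q - 1) // 2
    lengths, connected = [], 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        lengths.extend(d for d in dists.values() if d > 0)
    connected = len(lengths) // 2
    cpl = float(np.sum(lengths) / (2 * connected)) if connected else float("nan")
    return NetworkSummary(
        mean_connectivity=mean_conn,
        hub_count=hubs,
        characteristic_path_length=cpl,
        mean_first_neighbors=mean_deg,
        threshold=threshold,
        connected_pair_fraction=connected / total_pairs if total_pairs else 0.0,
    )


def assemble_dragon(
    recipe: DragonRecipe,
    matrices: Mapping[str, CorrelationMatrix] | Mapping[str, Mapping[str, CorrelationMatrix]] | None = None,
    data_matrices: Mapping[str, np.ndarray] | None = None,
    extra_blocks: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> list[DragonVector]:
    """Build one dragon vector per object according to ``recipe``.

    * ``dragon1``: ``[snake | means | variances]`` — needs per-object
      ``data_matrices`` (variables x repeats) from which the matrix,
      means, and variances are computed.
    * ``dragon2``: ``[snake | network summary fields]`` — needs
      per-object ``matrices``.
    * ``dragon3``: ``[snake(site1) | snake(site2) | ...]`` — ``matrices``
      maps object id -> {site -> CorrelationMatrix}; site order follows
      ``recipe.sites``.
    * ``dragon4``: arbitrary ordered named blocks from ``extra_blocks``
      (object id -> {block name -> vector}), ordered by ``recipe.blocks``.
    """
    tag = recipe.type_tag
    dragons: list[DragonVector] = []

    if tag == "dragon1":
        if not data_matrices:
            raise AssemblyError("dragon1 requires per-object data matrices")
        for oid, X in data_matrices.items():
            M, means, variances = matrix_from_data(X, name=str(oid))
            s = snake(M, recipe.ordering)
            dragons.append(
                DragonVector(
                    str(oid),
                    [
                        ("snake", "snake", s.values),
                        ("means", "means", means),
                        ("variances", "variances", variances),
                    ],
                )
            )
        return dragons

    if tag == "dragon2":
        if not matrices:
            raise AssemblyError("dragon2 requires per-object matrices")
        for oid, M in matrices.items():
            s = snake(M, recipe.ordering)
            summ = network_summaries(M, recipe.threshold)
            dragons.append(
                DragonVector(
                    str(oid),
                    [
                        ("snake", "snake", s.values),
                        ("network-summary", "network-summary", summ.as_vector()),
                    ],
                )
            )
        return dragons

    if tag == "dragon3":
        if not matrices or not recipe.sites:
            raise AssemblyError("dragon3 requires per-object site matrices and recipe.sites")
        for oid, sites in matrices.items():
            segs = []
            for site in recipe.sites:
                if site not in sites:
                    raise AssemblyError(f"object {oid} is missing block {site!r}")
                segs.append((site, "snake", snake(sites[site], recipe.ordering).values))
            dragons.append(DragonVector(str(oid), segs))
        return dragons

    if tag == "dragon4":
        if not extra_blocks or not recipe.blocks:
            raise AssemblyError("dragon4 requires extra_blocks and recipe.blocks")
        for oid, blocks in extra_blocks.items():
            segs = []
            for blk in recipe.blocks:
                if blk not in blocks:
                    raise AssemblyError(f"object {oid} is missing block {blk!r}")
                segs.append((blk, "extra", np.asarray(blocks[blk], dtype=float)))
            dragons.append(DragonVector(str(oid), segs))
        return dragons

    raise AssemblyError(f"unknown dragon recipe {tag!r}")


@dataclass
class ScalingTransform:
    """Recorded centering/scaling so held-out objects can be mapped too."""

    means: np.ndarray
    scales: np.ndarray  # one scale per coordinate (constant within a segment)
    policy: str

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.policy == "none":
            return np.asarray(values, dtype=float)
        return (np.asarray(values, dtype=float) - self.means) / self.scales


def _as_matrix(vectors: Sequence[SnakeVector | DragonVector]) -> tuple[np.ndarray, dict[str, slice]]:
    spans = vectors[0].segment_spans
    for v in vectors[1:]:
        if v.segment_spans != spans:
            raise AssemblyError("vectors have inconsistent segment layouts")
    return np.stack([v.values for v in vectors]), spans


def center_scale(
    vectors: Sequence[SnakeVector | DragonVector] | np.ndarray,
    policy: str = "per-segment",
    reference_ids: Sequence[str] | None = None,
    segment_spans: Mapping[str, slice] | None = None,
) -> tuple[np.ndarray, ScalingTransform]:
    """Center each coordinate and equalize segment scales.

    Every coordinate is centered by its mean over the reference objects
    (the whole cohort by default, or a control subset via
    ``reference_ids``).  Under the default ``per-segment`` policy each
    coordinate is then divided by the square root of the *mean* of the
    per-coordinate unbiased variances within its segment, so a single
    scale applies per segment and the coordinates of a segment keep
    their relative magnitudes.  ``per-coordinate`` z-scores every
    coordinate; ``none`` is the identity.
    """
    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=float)
        spans = dict(segment_spans) if segment_spans else {"all": slice(0, X.shape[1])}
        ids = [str(i) for i in range(X.shape[0])]
    else:
        X, spans = _as_matrix(list(vectors))
        ids = [v.object_id or str(i) for i, v in enumerate(vectors)]
    if X.shape[0] < 2:
        raise ScalingError("need at least 2 objects")
    if policy == "none":
        t = ScalingTransform(np.zeros(X.shape[1]), np.ones(X.shape[1]), "none")
        return X.copy(), t
    if reference_ids is not None:
        mask = np.isin(np.array(ids), np.array(list(reference_ids)))
        if not mask.any():
            raise ScalingError("reference subset is empty")
        ref = X[mask]
    else:
        ref = X
    means = ref.mean(axis=0)
    variances = ref.var(axis=0, ddof=1)
    scales = np.empty(X.shape[1])
    if policy == "per-segment":
        for name, sl in spans.items():
            avg_var = float(variances[sl].mean())
            if avg_var == 0:
                raise ScalingError(f"segment {name!r} has zero average variance")
            scales[sl] = np.sqrt(avg_var)
    elif policy == "per-coordinate":
        if np.any(variances == 0):
            bad = [n for n, sl in spans.items() if np.any(variances[sl] == 0)]
            raise ScalingError(f"zero-variance coordinate in segment(s) {bad}")
        scales = np.sqrt(variances)
    else:
        raise ScalingError(f"unknown scaling policy {policy!r}")
    t = ScalingTransform(means, scales, policy)
    return (X - means) / scales, t


@dataclass
class PCAResult:
    scores: np.ndarray  # N x m (weighted if requested)
    loadings: np.ndarray  # m x L
    explained_fractions: np.ndarray
    weighting: str


def pca_reduce(
    X: np.ndarray,
    variance_cutoff: float | None = 0.9,
    n_components: int | None = None,
    weighting: str = "none",
) -> PCAResult:
    """Project vectors onto principal components, optionally weighting
    each score by the fraction of variance its component explains.

    Components are retained up to ``variance_cutoff`` cumulative
    explained variance (default 90%), or exactly ``n_components`` if
    given (clipped to min(N-1, L) with a warning).
    """
    X = np.asarray(X, dtype=float)
    n, L = X.shape
    max_m = min(n - 1, L) if n > 1 else 1
    if n_components is not None:
        if n_components > max_m:
            warnings.warn(
                f"requested {n_components} components, reducing to {max_m}"
            )
        m = min(n_components, max_m)
    else:
        m = max_m
    pca = PCA(n_components=m, svd_solver="full")
    scores = pca.fit_transform(X)
    fractions = pca.explained_variance_ratio_
    if n_components is None and variance_cutoff is not None:
        keep = int(np.searchsorted(np.cumsum(fractions), variance_cutoff) + 1)
        keep = min(keep, m)
        scores, fractions = scores[:, :keep], fractions[:keep]
        pca_components = pca.components_[:keep]
    else:
        pca_components = pca.components_
    if weighting == "variance-explained":
        scores = scores * fractions
    elif weighting != "none":
        raise VectorizeError(f"unknown weighting {weighting!r}")
    return PCAResult(scores, pca_components, fractions, weighting)
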