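"""Classical pairwise statistics for comparing correlation matrices.

These are the reductionist baselines from evolutionary quantitative
genetics, each collapsing the difference between two matrices into a
single number:

* **random skewers (RS)** — both matrices respond to the same random
  selection vectors ("skewers"); similar matrices produce correlated
  response vectors.  Similarity is the mean Pearson correlation of the
  responses over many skewers; distance is ``1 - similarity``.
* **T statistic** — the sum of absolute element-wise differences over
  the upper off-diagonal triangle (each unordered pair once).
* **S1 statistic** — how well each matrix's eigenvectors explain the
  variance of the other.  Garcia's original S1 is published elsewhere;
  the formula here is an operationalization of its verbal definition:
  ``S1 = sum_k(|lam_k^A - e_k^A' B e_k^A| + |lam_k^B - e_k^B' A e_k^B|)
  / (tr A + tr B)``, which is symmetric and zero iff each eigenbasis
  explains the other matrix's variance exactly as its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import CorrelationMatrix, MatrixCollection

METHODS = ("random-skewers", "t-statistic", "s1")


class DistanceError(Exception):
    pass


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, CorrelationMatrix) else np.asarray(M, dtype=float)


def _check_pair(A: np.ndarray, B: np.ndarray) -> int:
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DistanceError(f"shape mismatch: {A.shape} vs {B.shape}")
    return A.shape[0]


def draw_skewers(rng: np.random.Generator, q: int, n_skewers: int) -> np.ndarray:
    """n_skewers x q unit-length vectors with iid uniform[-1, 1] entries."""
    S = rng.uniform(-1.0, 1.0, size=(n_skewers, q))
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return S / norms


def _row_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(Yc, axis=1)
    if np.any(denom == 0):
        raise DistanceError("degenerate (constant) response vector in RS")
    return np.einsum("ij,ij->i", Xc, Yc) / denom


def random_skewers_similarity(
    A, B, n_skewers: int = 100, rng_seed: int | np.random.Generator = 0
) -> float:
    """Mean correlation of the two matrices' responses to shared skewers.

    Pearson correlation is invariant to the scale of the responses, so
    whether the skewers are unit-normalized before multiplication does
    not change the result; they are normalized here as is standard.
    """
    A, B = _values(A), _values(B)
    q = _check_pair(A, B)
    if q < 3:
        raise DistanceError(
            "random skewers needs q >= 3 (correlation of length-2 responses is degenerate)"
        )
    if n_skewers < 1:
        raise DistanceError("n_skewers must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    S = draw_skewers(rng, q, n_skewers)
    return float(_row_pearson(S @ A, S @ B).mean())


def t_distance(A, B) -> float:
    """Sum of |A_ij - B_ij| over the upper off-diagonal triangle."""
    A, B = _values(A), _values(B)
    q = _check_pair(A, B)
    iu = np.triu_indices(q, 1)
    return float(np.abs(A[iu] - B[iu]).sum())


def s1_distance(A, B) -> float:
    """Cross-explained-variance divergence (S1 operationalization)."""
    A, B = _values(A), _values(B)
    _check_pair(A, B)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise DistanceError("non-finite entries; cannot diagonalize")
    lam_a, E_a = np.linalg.eigh(A)
    lam_b, E_b = np.linalg.eigh(B)
    cross_ab = np.einsum("ik,ij,jk->k", E_a, B, E_a)  # e_k^A' B e_k^A
    cross_ba = np.einsum("ik,ij,jk->k", E_b, A, E_b)
    total = np.trace(A) + np.trace(B)
    return float(
        (np.abs(lam_a - cross_ab).sum() + np.abs(lam_b - cross_ba).sum()) / total
    )


@dataclass
class PairwiseDistanceMatrix:
    object_ids: list[str]
    values: np.ndarray
    method_tag: str
    n_skewers: int | None = None
    seed: int | None = None


def pairwise(
    collection: MatrixCollection,
    method: str = "t-statistic",
    n_skewers: int = 100,
    rng_seed: int = 0,
) -> PairwiseDistanceMatrix:
    """All-pairs distance matrix over a collection.

    RS draws an independent skewer substream per unordered pair, keyed
    ``(seed, i, j)`` with i < j, so results do not depend on evaluation
    order and d(A,B) = d(B,A) exactly.  RS distance is 1 - similarity.
    """
    N = len(collection)
    if N < 2:
        raise DistanceError("need at least 2 objects")
    if method not in METHODS:
        raise DistanceError(f"unknown method {method!r}; choose from {METHODS}")
    D = np.zeros((N, N))
    mats = [m.values for m in collection.matrices]
    for i in range(N):
        for j in range(i + 1, N):
            try:
                if method == "random-skewers":
                    rng = np.random.default_rng([rng_seed, i, j])
                    d = 1.0 - random_skewers_similarity(
                        mats[i], mats[j], n_skewers, rng
                    )
                elif method == "t-statistic":
                    d = t_distance(mats[i], mats[j])
                else:
                    d = s1_distance(mats[i], mats[j])
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({collection.object_ids[i]}, {collection.object_ids[j]}): {exc}"
                ) from exc
            D[i, j] = D[j, i] = d
    return PairwiseDistanceMatrix(
        list(collection.object_ids),
        D,
        method,
        n_skewers=n_skewers if method == "random-skewers" else None,
        seed=rng_seed if method == "random-skewers" else None,
    )
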