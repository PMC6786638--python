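"""Scoring and characterization of clusterings.

Covers: confusion matrices and permutation-minimized misclassification
error against known labels; cluster characterization by external
covariates with test routing (chi-square for categorical, ANOVA or
Kruskal-Wallis for continuous depending on a Shapiro-Wilk normality
screen) under Benjamini-Hochberg FDR control; element-wise and
subnetwork-block differences between the mean matrices of two clusters;
and Shannon diversity indices of abundance profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .matrix_io import CorrelationMatrix, MatrixCollection


class EvaluateError(Exception):
    pass


@dataclass
class ConfusionMatrix:
    true_labels: list
    predicted_labels: list
    counts: np.ndarray  # rows = true, cols = predicted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.true_labels, columns=self.predicted_labels)


def confusion_and_misclassification(
    true_labels, predicted_labels
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and misclassification error under the best
    bijection between predicted and true cluster labels.

    Cluster labels are arbitrary names, so the error is minimized over
    all assignments of predicted clusters to true clusters (Hungarian
    algorithm on the padded contingency table); it is therefore
    invariant to any relabeling of the predicted clusters.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.size == 0:
        raise EvaluateError("label vectors must be equal-length and non-empty")
    t_vals, p_vals = list(np.unique(t)), list(np.unique(p))
    counts = np.zeros((len(t_vals), len(p_vals)), dtype=int)
    for i, tv in enumerate(t_vals):
        for j, pv in enumerate(p_vals):
            counts[i, j] = int(np.sum((t == tv) & (p == pv)))
    side = max(len(t_vals), len(p_vals))
    padded = np.zeros((side, side), dtype=int)
    padded[: len(t_vals), : len(p_vals)] = counts
    rows, cols = linear_sum_assignment(-padded)
    matched = int(padded[rows, cols].sum())
    error = 1.0 - matched / t.size
    return ConfusionMatrix(t_vals, p_vals, counts), float(error)


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up adjusted p-values and rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise EvaluateError("p-values must be finite and in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def characterize_clusters(
    covariates: pd.DataFrame,
    labels,
    q_fdr: float = 0.05,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each external covariate for differences across clusters.

    Categorical variables get a chi-square test of the contingency
    table.  Continuous variables are screened per cluster with
    Shapiro-Wilk at ``normality_alpha``; if every cluster looks normal,
    one-way ANOVA is used, otherwise Kruskal-Wallis.  Raw p-values are
    jointly BH-adjusted across all tested variables.  Constant or
    too-sparse variables are skipped (test = 'skipped').
    """
    labels = np.asarray(labels)
    if len(labels) != len(covariates):
        raise EvaluateError("labels and covariate rows must align")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise EvaluateError("need at least 2 clusters")
    records = []
    for col in covariates.columns:
        series = covariates[col]
        keep = series.notna().to_numpy()
        vals, labs = series[keep], labels[keep]
        rec = {"variable": col, "test": None, "statistic": np.nan, "p": np.nan, "summary": None}
        if keep.sum() < len(clusters) + 1 or vals.nunique() < 2:
            rec["test"] = "skipped"
            records.append(rec)
            continue
        is_categorical = (
            not pd.api.types.is_numeric_dtype(vals)
            or pd.api.types.is_bool_dtype(vals)
        )
        if is_categorical:
            table = pd.crosstab(vals, labs)
            chi2, p, _, _ = stats.chi2_contingency(table)
            pct = table.div(table.sum(axis=0), axis=1) * 100
            rec.update(
                test="chi-square",
                statistic=float(chi2),
                p=float(p),
                summary={str(c): dict(pct[c].round(1)) for c in table.columns},
            )
        else:
            groups = [vals[labs == c].to_numpy(dtype=float) for c in clusters]
            if any(len(g) < 2 or np.ptp(g) == 0 for g in groups):
                rec["test"] = "skipped"
                records.append(rec)
                continue
            normal = all(
                len(g) < 3 or stats.shapiro(g).pvalue >= normality_alpha for g in groups
            )
            if normal:
                stat, p = stats.f_oneway(*groups)
                rec["test"] = "anova"
            else:
                stat, p = stats.kruskal(*groups)
                rec["test"] = "kruskal-wallis"
            rec["statistic"], rec["p"] = float(stat), float(p)
            rec["summary"] = {
                str(c): f"{g.mean():.3f}(±{g.std(ddof=1):.3f})"
                for c, g in zip(clusters, groups)
            }
        records.append(rec)
    out = pd.DataFrame(records)
    tested = out["test"].notna() & (out["test"] != "skipped")
    out["p_adjusted"] = np.nan
    out["significant"] = False
    if tested.any():
        adj, rej = benjamini_hochberg(out.loc[tested, "p"].to_numpy(), q_fdr)
        out.loc[tested, "p_adjusted"] = adj
        out.loc[tested, "significant"] = rej
    return out


@dataclass
class ElementwiseResult:
    mean_cluster1: np.ndarray
    mean_cluster2: np.ndarray
    difference: np.ndarray  # cluster2 - cluster1
    significant_mask: np.ndarray  # boolean, symmetric, zero diagonal
    p_values: np.ndarray  # per upper-triangle element (NaN where skipped)
    p_adjusted: np.ndarray
    n_significant: int
    n_tested: int


def elementwise_matrix_tests(
    collection: MatrixCollection, labels, q_fdr: float = 0.05
) -> ElementwiseResult:
    """Welch t-test per off-diagonal element between two clusters of
    matrices, BH-corrected across all q(q-1)/2 elements.

    Zero-variance elements in both clusters are skipped (NaN p, not
    significant).  Returns per-cluster mean matrices, the cluster2 -
    cluster1 difference, and the boolean FDR-significance mask.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) != 2:
        raise EvaluateError("element-wise tests require exactly 2 clusters")
    stacked = collection.stacked()
    g1 = stacked[labels == clusters[0]]
    g2 = stacked[labels == clusters[1]]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise EvaluateError("each cluster needs at least 2 matrices")
    q = collection.q
    iu = np.triu_indices(q, 1)
    x1, x2 = g1[:, iu[0], iu[1]], g2[:, iu[0], iu[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x1, x2, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (np.ptp(x1, axis=0) == 0) & (np.ptp(x2, axis=0) == 0)
    p[degenerate] = np.nan
    testable = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    sig = np.zeros_like(p, dtype=bool)
    if testable.any():
        adj[testable], sig[testable] = benjamini_hochberg(p[testable], q_fdr)
    mean1, mean2 = g1.mean(axis=0), g2.mean(axis=0)
    mask = np.zeros((q, q), dtype=bool)
    mask[iu] = sig
    mask |= mask.T
    return ElementwiseResult(
        mean_cluster1=mean1,
        mean_cluster2=mean2,
        difference=mean2 - mean1,
        significant_mask=mask,
        p_values=p,
        p_adjusted=adj,
        n_significant=int(sig.sum()),
        n_tested=int(testable.sum()),
    )


@dataclass
class BlockDifference:
    block_pair: tuple[str, str]
    c1: float
    c2: float
    mean_difference: float  # c2 - c1
    relative_difference: float | None  # (c2 - c1)/c1, None when c1 == 0
    n_elements: int


def subnetwork_block_differences(
    mean1: CorrelationMatrix | np.ndarray,
    mean2: CorrelationMatrix | np.ndarray,
    partition: dict[str, list[int]] | dict[str, list[str]],
    labels: list[str] | None = None,
) -> list[BlockDifference]:
    """Mean connectivity difference per subnetwork block pair.

    ``partition`` maps block names to member nodes (indices, or label
    strings resolved against ``labels`` / the matrix's own labels); it
    must cover all nodes disjointly.  For each unordered block pair
    (within-block included) the block value c is the mean of the
    off-diagonal elements with one endpoint in each block, each
    unordered element pair counted once.  Singleton within-block cells
    have no off-diagonal elements and are skipped.
    """
    V1 = mean1.values if isinstance(mean1, CorrelationMatrix) else np.asarray(mean1, dtype=float)
    V2 = mean2.values if isinstance(mean2, CorrelationMatrix) else np.asarray(mean2, dtype=float)
    if V1.shape != V2.shape:
        raise EvaluateError("mean matrices differ in shape")
    q = V1.shape[0]
    if labels is None and isinstance(mean1, CorrelationMatrix):
        labels = mean1.labels
    idx_of: dict[str, list[int]] = {}
    for name, members in partition.items():
        idx = [
            m if isinstance(m, (int, np.integer)) else labels.index(m)  # type: ignore[union-attr]
            for m in members
        ]
        idx_of[name] = sorted(idx)
    covered = sorted(i for idx in idx_of.values() for i in idx)
    if covered != list(range(q)):
        raise EvaluateError("partition must cover all nodes exactly once")
    names = list(idx_of)
    out: list[BlockDifference] = []
    for ai, a in enumerate(names):
        for b in names[ai:]:
            ia, ib = idx_of[a], idx_of[b]
            if a == b:
                pairs = [(i, j) for x, i in enumerate(ia) for j in ia[x + 1 :]]
            else:
                pairs = [(i, j) for i in ia for j in ib]
            if not pairs:
                continue  # singleton within-block cell: no off-diagonal elements
            rows = np.array([p[0] for p in pairs])
            cols = np.array([p[1] for p in pairs])
            c1 = float(V1[rows, cols].mean())
            c2 = float(V2[rows, cols].mean())
            rel = (c2 - c1) / c1 if c1 != 0 else None
            out.append(
                BlockDifference((a, b), c1, c2, c2 - c1, rel, len(pairs))
            )
    return out


def shannon_index(abundances) -> tuple[float, float | None]:
    """Shannon diversity SI = -sum r_i ln r_i and normalized SI/ln(R).

    Abundances must be non-negative and sum to 1 (within 1e-9); zero
    abundances contribute 0 by the usual limit convention.  The
    normalized index is undefined (None) for a single taxon, where SI
    is 0.
    """
    r = np.asarray(abundances, dtype=float)
    if r.ndim != 1 or r.size < 1:
        raise EvaluateError("abundance profile must be a non-empty 1-D vector")
    if np.any(r < 0):
        raise EvaluateError("negative abundance")
    if abs(r.sum() - 1.0) > 1e-9:
        raise EvaluateError(f"abundances sum to {r.sum()}, not 1")
    nz = r[r > 0]
    si = float(-(nz * np.log(nz)).sum())
    R = r.size
    normalized = si / np.log(R) if R >= 2 else None
    return si, normalized
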