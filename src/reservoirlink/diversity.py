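"""Alpha/beta diversity, ordination and permutation tests.

Distance metrics: Bray-Curtis and Jaccard (presence-absence) on count
tables, and unweighted / (normalized) weighted UniFrac given a rooted tree.
All four return a labelled, symmetric, zero-diagonal
:class:`skbio.DistanceMatrix` with values in [0, 1].

PERMANOVA comes in two flavours: the classic one-way pseudo-F with label
permutation (optionally exact enumeration of distinct group assignments),
and a crossed two-factor partition (main effects + interaction) built on
the Gower-centered inner-product matrix with sequential sums of squares of
hat-matrix projections, permuting raw observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from statsmodels.stats.multitest import multipletests

from .core_data import CountTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "pairwise_distance",
    "shannon",
    "pcoa",
    "permanova",
    "permanova_crossed",
    "bh_fdr",
]

METRICS = ("bray_curtis", "jaccard_pa", "unweighted_unifrac", "weighted_unifrac")


def pairwise_distance(
    table: CountTable,
    metric: str,
    tree: TreeNode | None = None,
    weighted_unifrac_normalized: bool = True,
) -> DistanceMatrix:
    """Pairwise sample dissimilarities under one of the four supported metrics.

    Bray-Curtis is computed on raw counts; Jaccard on presence (count >= 1).
    The UniFrac metrics require ``tree`` to cover every taxon with a non-zero
    count. Weighted UniFrac uses the normalized, [0, 1]-bounded variant by
    default.
    """
    counts = table.counts
    ids = table.sample_ids
    if metric == "bray_curtis":
        vec = pdist(counts.astype(float), metric="braycurtis")
        return DistanceMatrix(squareform(vec), ids)
    if metric == "jaccard_pa":
        vec = pdist(counts > 0, metric="jaccard")
        return DistanceMatrix(squareform(vec), ids)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        tips = {t.name for t in tree.tips()}
        present = set(np.asarray(table.taxon_ids)[counts.sum(axis=0) > 0])
        missing = sorted(present - tips)
        if missing:
            raise ValueError(f"tree is missing tip(s): {missing}")
        kwargs = {}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = weighted_unifrac_normalized
        return beta_diversity(
            metric, counts, ids=ids, taxa=table.taxon_ids, tree=tree, **kwargs
        )
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def shannon(table: CountTable, base: float = 2.0) -> pd.Series:
    """Per-sample Shannon entropy H = -sum p_i log_base p_i over detected taxa."""
    rel = table.data.div(table.sample_sums(), axis=0)
    return pd.Series(
        entropy(rel.to_numpy(), base=base, axis=1), index=table.data.index, name="shannon"
    )


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: per-sample coordinates on positive axes, eigenvalues, proportions."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over retained (positive) axes


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps axes with eigenvalue
    > eps; negative eigenvalues are reported in ``eigenvalues`` but their
    axes are dropped (no Lingoes/Cailliez correction).
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    a = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    g = J @ a @ J
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eps
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    pos_sum = vals[keep].sum()
    prop = vals[keep] / pos_sum if pos_sum > 0 else vals[keep]
    cols = [f"PC{i+1}" for i in range(int(keep.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=vals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    """Permutation-test result: pseudo-F, effect size R^2, and permutation p."""

    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    q_value: float | None = None
    df: tuple[int, int] | None = None


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, 1).sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, a: int, n: int) -> tuple[float, float]:
    ss_total, ss_within = _group_ss(d2, labels)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix,
    grouping: pd.Series | np.ndarray | list,
    n_permutations: int = 1000,
    seed: int | None = None,
    method: str = "random",
) -> PermanovaResult:
    """One-way PERMANOVA with label-permutation p-value.

    p uses the +1/+1 convention (the observed statistic counts as one
    permutation), so p is never 0. ``method="exact"`` enumerates every
    distinct assignment of samples to group sizes instead of sampling
    permutations — feasible for small n and preferred there, since the
    resulting p is exact.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.reindex(list(dm.ids)).to_numpy()
    labels = np.asarray(grouping)
    n = len(labels)
    if n != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) with a single member: {bad}")
    a = len(uniq)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _pseudo_f(d2, labels, a, n)

    if method == "exact":
        perms = _distinct_assignments(labels)
        hits = sum(
            1 for lab in perms if _pseudo_f(d2, lab, a, n)[0] >= f_obs - 1e-12
        )
        p = hits / len(perms)
        n_perm = len(perms)
    elif method == "random":
        rng = np.random.default_rng(seed)
        hits = 0
        lab = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(lab)
            if _pseudo_f(d2, lab, a, n)[0] >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
        n_perm = n_permutations
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(
        factor="grouping", pseudo_f=f_obs, r_squared=r2, p_value=p,
        n_permutations=n_perm, seed=seed, df=(a - 1, n - a),
    )


def _distinct_assignments(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct ways to assign the observed label multiset to positions."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    if comb(n, int(counts[0])) > 200_000:
        raise ValueError("too many assignments for exact enumeration")
    out: list[np.ndarray] = []

    def rec(positions: tuple[int, ...], k: int, current: np.ndarray) -> None:
        if k == len(uniq) - 1:
            lab = current.copy()
            lab[list(positions)] = uniq[k]
            out.append(lab)
            return
        for chosen in combinations(positions, int(counts[k])):
            lab = current.copy()
            lab[list(chosen)] = uniq[k]
            rec(tuple(p for p in positions if p not in chosen), k + 1, lab)

    rec(tuple(range(n)), 0, np.empty(n, dtype=uniq.dtype))
    return out


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _gower(dm: DistanceMatrix) -> np.ndarray:
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ a @ J


def permanova_crossed(
    dm: DistanceMatrix,
    factor_a: pd.Series,
    factor_b: pd.Series,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict[str, PermanovaResult]:
    """Two-factor crossed PERMANOVA (A, B, A:B) with sequential sums of squares.

    Distance-based multivariate ANOVA on the Gower-centered matrix G:
    each term's SS is tr((H_k - H_{k-1}) G) for the nested sequence of hat
    matrices intercept ⊂ A ⊂ A+B ⊂ A+B+A:B; pseudo-F uses the full-model
    residual. Significance comes from permuting raw observations (rows and
    columns of G jointly). The design need not be balanced, but the two
    factors must not be aliased.
    """
    ids = list(dm.ids)
    fa = pd.Series(factor_a).reindex(ids) if isinstance(factor_a, pd.Series) else pd.Series(list(factor_a), index=ids)
    fb = pd.Series(factor_b).reindex(ids) if isinstance(factor_b, pd.Series) else pd.Series(list(factor_b), index=ids)
    if fa.isna().any() or fb.isna().any():
        raise ValueError("factors must cover every sample in the distance matrix")
    n = len(ids)
    A = pd.get_dummies(fa, drop_first=True).to_numpy(float)
    B = pd.get_dummies(fb, drop_first=True).to_numpy(float)
    a_lv, b_lv = fa.nunique(), fb.nunique()
    if a_lv < 2:
        raise ValueError("factor A must vary")
    b_constant = b_lv < 2  # degenerates to one-way PERMANOVA on A
    AB = np.hstack([
        (A[:, [i]] * B[:, [j]]) for i in range(A.shape[1]) for j in range(B.shape[1])
    ]) if A.shape[1] and B.shape[1] else np.empty((n, 0))
    ones = np.ones((n, 1))
    X0 = ones
    X1 = np.hstack([ones, A])
    X2 = np.hstack([ones, A, B])
    X3 = np.hstack([ones, A, B, AB])
    ranks = [np.linalg.matrix_rank(X) for X in (X0, X1, X2, X3)]
    df_a, df_b = ranks[1] - ranks[0], ranks[2] - ranks[1]
    df_ab = ranks[3] - ranks[2]
    df_res = n - ranks[3]
    if df_a == 0 or (df_b == 0 and not b_constant):
        raise ValueError("confounded (aliased) factors: a term has zero degrees of freedom")
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (one observation per cell?)")
    hats = [_hat(X) for X in (X0, X1, X2, X3)]
    G = _gower(dm)

    term_dfs = [df_a, df_b, df_ab]

    def terms(Gp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = [float(np.sum(H * Gp)) for H in hats]  # tr(H G), H symmetric
        ss = np.array([tr[1] - tr[0], tr[2] - tr[1], tr[3] - tr[2],
                       float(np.trace(Gp)) - tr[3]])
        ms_res = ss[3] / df_res
        f = np.array([
            (ss[i] / term_dfs[i]) / ms_res if term_dfs[i] > 0 else np.nan
            for i in range(3)
        ])
        return f, ss

    f_obs, ss = terms(G)
    ss_total = float(np.trace(G))
    rng = np.random.default_rng(seed)
    hits = np.zeros(3)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm, _ = terms(G[np.ix_(perm, perm)])
        with np.errstate(invalid="ignore"):
            hits += np.nan_to_num(f_perm >= f_obs - 1e-12)
    p = (1 + hits) / (n_permutations + 1)
    names = [str(getattr(factor_a, "name", None) or "A"),
             str(getattr(factor_b, "name", None) or "B")]
    names.append(f"{names[0]}:{names[1]}")
    dfs = [(df_a, df_res), (df_b, df_res), (df_ab, df_res)]
    return {
        name: PermanovaResult(
            factor=name, pseudo_f=float(f_obs[i]), r_squared=float(ss[i] / ss_total),
            p_value=float(p[i]), n_permutations=n_permutations, seed=seed, df=dfs[i],
        )
        for i, name in enumerate(names)
        if term_dfs[i] > 0
    }


def bh_fdr(pvalues: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
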