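"""Environmental-reservoir signal: residual-source correlations and Mantel tests.

Two complementary questions about where host-associated bacteria come from:

1. Are taxa that sit above the neutral occurrence-abundance curve on hosts
   (positive residuals) also the taxa that are common/abundant in the
   surrounding water?  Answered by a Spearman correlation between neutral-
   model residuals and per-taxon water occurrence or mean abundance, with
   taxa absent from water entering at 0 rather than being dropped.

2. Do between-site differences in host communities mirror between-site
   differences in water communities?  Answered by a Mantel test between the
   site-level water distance matrix and the site-averaged host (polyp)
   distance matrix, one-tailed for positive association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CountTable
from .diversity import DistanceMatrix
from .neutral_model import occurrence_abundance

__all__ = [
    "MantelResult",
    "source_stats",
    "residual_source_correlation",
    "site_average_polyp_distance",
    "site_water_profiles",
    "mantel_test",
]


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistics: r (Pearson on off-diagonals), z (raw cross-product sum), p."""

    r: float
    z: float
    p_value: float
    n_permutations: int
    seed: int | None = None


def source_stats(water: CountTable, taxa: pd.Index | None = None) -> pd.DataFrame:
    """Per-taxon occurrence fraction and mean relative abundance in water samples.

    ``taxa`` extends the index to host-side taxa never seen in water, which
    enter with occurrence and abundance 0 (dropping them would condition on
    the outcome being tested).
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pf = occurrence_abundance(water)
    pf = pf.rename(columns={"p": "water_abundance", "f": "water_occurrence"})
    if taxa is not None:
        pf = pf.reindex(taxa.union(pf.index)).fillna(0.0)
    return pf[["water_occurrence", "water_abundance"]]


def residual_source_correlation(
    residuals: pd.Series,
    water_stat: pd.Series,
    method: str = "asymptotic",
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman correlation between neutral-model residuals and a water statistic.

    Mid-ranks handle ties; p comes from the large-sample t approximation
    (two-sided), or from label permutation when ``method="permutation"``. Taxa missing from ``water_stat`` count as 0.
    """
    resid = residuals.dropna()
    stat = water_stat.reindex(resid.index).fillna(0.0)
    if len(resid) < 4:
        raise ValueError("need at least 4 shared taxa")
    rho, p = stats.spearmanr(resid.to_numpy(), stat.to_numpy())
    if method == "permutation":
        rng = np.random.default_rng(seed)
        x = resid.to_numpy()
        y = stat.to_numpy().copy()
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(y)
            if abs(stats.spearmanr(x, y).statistic) >= abs(rho) - 1e-12:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def site_average_polyp_distance(
    dm: DistanceMatrix, site_of: Mapping[str, str] | pd.Series
) -> DistanceMatrix:
    """Collapse a polyp-level distance matrix to sites by averaging between-site entries.

    Entry (s, t) is the mean of d(a, b) over polyps a in s, b in t; the
    diagonal is 0. Site order is sorted for determinism.
    """
    site_of = pd.Series(dict(site_of)) if not isinstance(site_of, pd.Series) else site_of
    ids = list(dm.ids)
    missing = [i for i in ids if i not in site_of.index]
    if missing:
        raise ValueError(f"samples without a site: {missing[:5]}")
    sites = sorted(site_of.loc[ids].unique())
    idx_of = {s: [k for k, i in enumerate(ids) if site_of[i] == s] for s in sites}
    empty = [s for s in sites if not idx_of[s]]
    if empty:
        raise ValueError(f"site(s) with no polyps: {empty}")
    d = np.asarray(dm.data)
    out = np.zeros((len(sites), len(sites)))
    for a, s in enumerate(sites):
        for b in range(a + 1, len(sites)):
            block = d[np.ix_(idx_of[s], idx_of[sites[b]])]
            out[a, b] = out[b, a] = block.mean()
    return DistanceMatrix(out, sites)


def site_water_profiles(water: CountTable, site_of: Mapping[str, str] | pd.Series) -> CountTable:
    """Average multiple water samples per site into one site-level count profile."""
    site_of = pd.Series(dict(site_of)) if not isinstance(site_of, pd.Series) else site_of
    grouped = water.data.groupby(by=lambda sid: site_of[sid]).sum()
    return CountTable(grouped.sort_index())


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two distance matrices over the same objects.

    r is the Pearson correlation of the lower-triangle entries (the primary,
    scale-free statistic); z is the raw sum of their cross-products. The
    null permutes the row/column order of d2 jointly; p follows the +1/+1
    convention, one-tailed ("greater") by default for the directional
    host-tracks-environment hypothesis.
    """
    ids1, ids2 = list(d1.ids), list(d2.ids)
    if ids1 != ids2:
        only1 = sorted(set(ids1) - set(ids2))
        only2 = sorted(set(ids2) - set(ids1))
        if only1 or only2:
            raise ValueError(
                f"label mismatch: only in d1 {only1[:5]}, only in d2 {only2[:5]}"
            )
        d2 = d2.filter(ids1)  # same labels, different order
    n = len(ids1)
    if n < 4:
        raise ValueError("need at least 4 objects")
    a = np.asarray(d1.data)
    b = np.asarray(d2.data)
    il = np.tril_indices(n, -1)
    x = a[il]

    def stat(mat: np.ndarray) -> float:
        return float(np.corrcoef(x, mat[il])[0, 1])

    r_obs = stat(b)
    z_obs = float(np.sum(x * b[il]))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = stat(b[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_perm >= r_obs - 1e-12
        elif alternative == "two-sided":
            hits += abs(r_perm) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + hits) / (n_permutations + 1)
    return MantelResult(r=r_obs, z=z_obs, p_value=p, n_permutations=n_permutations,
                        seed=seed)
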