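"""Water-exchange experiment analytics.

Per-population, per-week native-vs-foreign contrasts on two beta-diversity
metrics with BH-FDR per population table; Shannon alpha-diversity
trajectories with per-week rank-sum tests; PC-1 volatility trajectories on a
pooled ordination; and presence-based gain/loss tallies against the shared
week-0 start.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CountTable, SampleMetadata, rarefy
from .diversity import DistanceMatrix, OrdinationResult, bh_fdr, permanova, shannon

__all__ = [
    "per_timepoint_permanova",
    "volatility_pc1",
    "alpha_trajectory",
    "gain_loss_sets",
]


def _design_frame(design: SampleMetadata) -> pd.DataFrame:
    df = design.indexed()
    if "timepoint" not in df.columns or df["timepoint"].isna().all():
        raise ValueError("longitudinal design requires a timepoint column")
    return df


def per_timepoint_permanova(
    distances: Mapping[str, DistanceMatrix],
    design: SampleMetadata,
    n_permutations: int = 1000,
    seed: int | None = None,
    include_start_contrasts: bool = True,
) -> pd.DataFrame:
    """Native-vs-foreign PERMANOVA per (population, week, metric), BH per population.

    ``distances`` maps metric name -> distance matrix over all samples.
    Every (population, week) cell needs both treatment groups; BH-FDR is
    applied within each population's table of weekly tests (the analysis
    block), with start-vs-treatment contrasts pooling weeks 1+ adjusted as
    their own family.
    """
    df = _design_frame(design)
    rng = np.random.default_rng(seed)
    rows = []
    for pop in sorted(df["population"].unique()):
        sub = df[df["population"] == pop]
        weeks = sorted(int(w) for w in sub["timepoint"].dropna().unique() if w > 0)
        for metric, dm in distances.items():
            for week in weeks:
                cell = sub[(sub["timepoint"] == week)
                           & (sub["treatment"].isin(["native", "foreign"]))]
                counts = cell["treatment"].value_counts()
                if set(counts.index) != {"native", "foreign"}:
                    raise ValueError(
                        f"empty design cell: population {pop}, week {week}"
                    )
                ids = list(cell.index)
                res = permanova(
                    dm.filter(ids), cell.loc[ids, "treatment"],
                    n_permutations=n_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                )
                rows.append({
                    "population": pop, "metric": metric, "contrast": "native_vs_foreign",
                    "week": week, "group1": "native", "group2": "foreign",
                    "pseudo_f": res.pseudo_f, "r_squared": res.r_squared,
                    "p": res.p_value,
                })
            if include_start_contrasts:
                for trt in ("native", "foreign"):
                    grp = sub[((sub["timepoint"] == 0))
                              | ((sub["treatment"] == trt) & (sub["timepoint"] > 0))]
                    labels = np.where(grp["timepoint"] == 0, "start", trt)
                    ids = list(grp.index)
                    res = permanova(
                        dm.filter(ids), pd.Series(labels, index=ids),
                        n_permutations=n_permutations,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    rows.append({
                        "population": pop, "metric": metric,
                        "contrast": "start_vs_treatment", "week": pd.NA,
                        "group1": "start", "group2": trt,
                        "pseudo_f": res.pseudo_f, "r_squared": res.r_squared,
                        "p": res.p_value,
                    })
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for (pop, contrast), idx in out.groupby(["population", "contrast"]).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"])
    return out


def volatility_pc1(
    ordination: OrdinationResult, design: SampleMetadata
) -> pd.DataFrame:
    """Group-mean PC-1 trajectory per (treatment, week) with SE and displacement.

    ``displacement`` is the week-to-week first difference of the group mean;
    missing weeks leave a gap (NaN displacement) rather than interpolating.
    """
    df = _design_frame(design)
    coords = ordination.coordinates
    shared = coords.index.intersection(df.index)
    merged = df.loc[shared].copy()
    merged["pc1"] = coords.loc[shared, "PC1"]
    rows = []
    for (pop, trt), grp in merged.groupby(["population", "treatment"]):
        weeks = sorted(int(w) for w in grp["timepoint"].dropna().unique())
        prev_week, prev_mean = None, None
        for w in weeks:
            vals = grp.loc[grp["timepoint"] == w, "pc1"]
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            disp = (mean - prev_mean) if (prev_week is not None and w == prev_week + 1) else np.nan
            rows.append({
                "population": pop, "treatment": trt, "week": w, "n": len(vals),
                "pc1_mean": mean, "pc1_se": se, "displacement": disp,
            })
            prev_week, prev_mean = w, mean
    return pd.DataFrame(rows)


def alpha_trajectory(
    table: CountTable,
    design: SampleMetadata,
    depth: int | None = None,
    seed: int = 0,
    base: float = 2.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Shannon entropy per sample (after rarefaction) plus per-week rank-sum tests.

    Samples are rarefied to ``depth`` (default: the minimum sample sum, the
    "minimum reads for the experiment" convention) before computing Shannon
    entropy. Per population and week, native vs foreign is compared with a
    two-sided Mann-Whitney rank-sum test, BH-adjusted across that
    population's weeks; groups under 3 samples are skipped with a notice row.
    """
    df = _design_frame(design)
    rare = rarefy(table, depth=depth, seed=seed)
    h = shannon(rare, base=base)
    rows = []
    for pop in sorted(df["population"].unique()):
        sub = df[df["population"] == pop]
        for week in sorted(int(w) for w in sub["timepoint"].dropna().unique() if w > 0):
            cell = sub[sub["timepoint"] == week]
            nat = h.reindex(cell.index[cell["treatment"] == "native"]).dropna()
            for_ = h.reindex(cell.index[cell["treatment"] == "foreign"]).dropna()
            if len(nat) < 3 or len(for_) < 3:
                rows.append({"population": pop, "week": week, "n_native": len(nat),
                             "n_foreign": len(for_), "statistic": np.nan, "p": np.nan,
                             "note": "skipped: group n < 3"})
                continue
            stat, p = stats.mannwhitneyu(nat, for_, alternative="two-sided")
            rows.append({"population": pop, "week": week, "n_native": len(nat),
                         "n_foreign": len(for_), "statistic": float(stat),
                         "p": float(p), "note": ""})
    tests = pd.DataFrame(rows)
    tests["q"] = np.nan
    for pop, idx in tests.groupby("population").groups.items():
        ok = tests.loc[idx, "p"].notna()
        sel = tests.loc[idx].index[ok]
        if len(sel):
            tests.loc[sel, "q"] = bh_fdr(tests.loc[sel, "p"])
    return h, tests


def gain_loss_sets(
    table: CountTable,
    design: SampleMetadata,
    prevalence_threshold: float = 0.5,
) -> pd.DataFrame:
    """Taxa gained/lost per (population, treatment, week) relative to week 0.

    A taxon is "present" in a group-week when detected in at least
    ``prevalence_threshold`` of that group's samples; gained = present now
    but not at the shared start, lost = the converse. Gained and lost sets
    are disjoint by construction.
    """
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence_threshold must be in (0, 1]")
    df = _design_frame(design)
    presence = table.data > 0
    rows = []
    for pop in sorted(df["population"].unique()):
        sub = df[df["population"] == pop]
        start_ids = sub.index[sub["timepoint"] == 0]
        if len(start_ids) == 0:
            raise ValueError(f"population {pop} has no week-0 samples")
        start_present = set(
            presence.columns[presence.loc[start_ids].mean(axis=0) >= prevalence_threshold]
        )
        for (trt, week), cell in sub[sub["timepoint"] > 0].groupby(["treatment", "timepoint"]):
            now = set(
                presence.columns[presence.loc[cell.index].mean(axis=0) >= prevalence_threshold]
            )
            gained = sorted(now - start_present)
            lost = sorted(start_present - now)
            rows.append({
                "population": pop, "treatment": trt, "week": int(week),
                "n_gained": len(gained), "n_lost": len(lost),
                "gained": gained, "lost": lost,
            })
    return pd.DataFrame(rows).sort_values(["population", "treatment", "week"]).reset_index(drop=True)
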