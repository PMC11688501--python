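"""Synthetic community generators with recorded ground truth.

These generators emulate the statistical structure of a freshwater
host-microbiome survey and a water-exchange experiment:

* a heavy-tailed (log-normal) bacterioplankton source pool;
* host communities assembled neutrally from that pool — per-taxon local
  relative abundance Beta(N m p_i, N m (1 - p_i)) distributed, then
  multinomial sequencing at depth N (the same beta approximation the
  neutral-model fit assumes, which makes parameter recovery a sharp test);
* a minority of injected non-neutral taxa whose occurrence is pushed above
  (host-favoured / environmentally sustained) or below (host-excluded) the
  neutral expectation;
* between-site compositional gradients shared by water and host samples,
  with hosts drawing on a mixture of a shared host-core community and their
  site's water pool;
* a five-week native/foreign water-exchange time-series in which rare-taxon
  identity turns over in the foreign group while the dominant abundance
  structure is conserved, a shared lab-shift hits every post-start sample,
  and one designated taxon rises in all groups by the final week.

Every generator is deterministic under a fixed seed, and every piece of
injected structure is recorded in a :class:`SyntheticTruth` for recovery
tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import CountTable, SampleMetadata
from .neutral_model import predict_occurrence

__all__ = [
    "SyntheticTruth",
    "generate_source_pool",
    "assemble_neutral_samples",
    "inject_nonneutral_taxa",
    "injection_candidates",
    "generate_paired_sites",
    "generate_exchange_timeseries",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset: parameters and injected structure."""

    m: float
    depth: int
    source_pool: pd.Series
    injected_over: frozenset = frozenset()
    injected_under: frozenset = frozenset()
    gradient_strength: float = 0.0
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(float(self.source_pool.sum()) - 1.0) > 1e-9:
            raise ValueError("source pool must sum to 1")
        if self.injected_over & self.injected_under:
            raise ValueError("injected over/under sets must be disjoint")


def generate_source_pool(
    n_taxa: int, sigma: float = 2.0, seed: int | np.random.Generator = 0,
    prefix: str = "t",
) -> pd.Series:
    """Log-normal relative-abundance source pool, normalized to sum 1.

    ``sigma`` is the log-scale shape: 2.0 gives the few-dominants/long-rare-
    tail profile typical of lake bacterioplankton; sigma -> 0 approaches a
    uniform pool.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    ids = [f"{prefix}{i:04d}" for i in range(n_taxa)]
    pool = pd.Series(raw / raw.sum(), index=ids)
    return pool


def _draw_local_abundance(
    pool: np.ndarray, m: float, N: int, rng: np.random.Generator
) -> np.ndarray:
    """One community's local relative abundances under the beta approximation."""
    a = N * m * pool
    b = N * m * (1.0 - pool)
    x = np.zeros_like(pool)
    pos = (a > 0) & (b > 0)
    x[pos] = rng.beta(a[pos], b[pos])
    x[(pool > 0) & (b <= 0)] = 1.0
    total = x.sum()
    if total == 0:  # pathological tiny pools; retry deterministic-ly
        x[np.argmax(pool)] = 1.0
        total = 1.0
    return x / total


def assemble_neutral_samples(
    pool: pd.Series,
    m: float,
    N: int,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    prefix: str = "S",
) -> tuple[CountTable, SyntheticTruth]:
    """Assemble communities neutrally from a source pool.

    Each sample's per-taxon relative abundance is Beta(N m p_i, N m (1-p_i))
    distributed, then N reads are drawn multinomially. Taxa with pool
    abundance 0 are never observed.
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if N < 100:
        raise ValueError("N must be >= 100")
    rng = np.random.default_rng(seed)
    p = pool.to_numpy(dtype=float)
    counts = np.empty((n_samples, len(p)), dtype=np.int64)
    for i in range(n_samples):
        x = _draw_local_abundance(p, m, N, rng)
        counts[i] = rng.multinomial(N, x)
        if counts[i].sum() == 0:  # cannot happen for N >= 100, defensive
            counts[i, np.argmax(p)] = N
    table = CountTable(
        pd.DataFrame(counts, index=[f"{prefix}{i:03d}" for i in range(n_samples)],
                     columns=list(pool.index))
    )
    truth = SyntheticTruth(
        m=m, depth=N, source_pool=pool,
        seed=seed if isinstance(seed, int) else None,
    )
    return table, truth


def injection_candidates(
    table: CountTable,
    m: float,
    N: int,
    effect: float,
    water_abundance: pd.Series | None = None,
    host_taxa: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Rank taxa eligible for over-/under-representation injection.

    A taxon is over-eligible when the neutral prediction leaves headroom
    (f_hat + effect <= 1) and under-eligible when f_hat >= effect. When
    ``water_abundance`` is given, over-candidates are ordered by decreasing
    water abundance (the water-enriched tail first); under-candidates are
    restricted to ``host_taxa`` (host-associated taxa rare or absent in
    water) when provided, mirroring host-restricted symbionts.
    """
    from .neutral_model import occurrence_abundance
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        pf = occurrence_abundance(table)
    fhat = pd.Series(predict_occurrence(pf["p"], m, N), index=pf.index)
    f = pf["f"]
    over_ok = pf.index[(fhat + effect <= 1.0) & (f < 1.0) & (f > 0)]
    under_ok = pf.index[(fhat - effect >= 0.0) & (f > 0)]
    if host_taxa is not None:
        under_ok = under_ok.intersection(pd.Index(host_taxa))
    if water_abundance is not None:
        wa = water_abundance.reindex(over_ok).fillna(0.0)
        over = list(wa.sort_values(ascending=False).index)
        wa_u = water_abundance.reindex(under_ok).fillna(0.0)
        under = list(wa_u.sort_values(ascending=True).index)
    else:
        over, under = sorted(over_ok), sorted(under_ok)
    under = [t for t in under if t not in set(over[: len(over)])]
    return over, under


def inject_nonneutral_taxa(
    table: CountTable,
    truth: SyntheticTruth,
    k_over: int,
    k_under: int,
    effect: float,
    seed: int | np.random.Generator = 0,
    over_candidates: Sequence[str] | None = None,
    under_candidates: Sequence[str] | None = None,
) -> tuple[CountTable, SyntheticTruth]:
    """Force k_over taxa above and k_under taxa below the neutral occurrence curve.

    Over-represented taxa gain single-read detections in randomly chosen
    samples until their occurrence exceeds the neutral prediction by at
    least ``effect`` (abundance impact kept minimal); under-represented
    taxa lose detections symmetrically. ``effect=0`` is an explicit no-op.
    Candidate lists, when given, are consumed in order (use
    :func:`injection_candidates` to encode a selection rule); otherwise
    eligible taxa are drawn at random. Labels are recorded in the returned
    truth.
    """
    if not 0 <= effect < 1:
        raise ValueError("effect must be in [0, 1)")
    if k_over + k_under > table.n_taxa / 10:
        raise ValueError("injected taxa must stay a minority (<= n_taxa/10)")
    if effect == 0 or (k_over == 0 and k_under == 0):
        return table, replace(truth, injected_over=frozenset(), injected_under=frozenset())
    rng = np.random.default_rng(seed)
    m, N = truth.m, truth.depth
    over_all, under_all = injection_candidates(table, m, N, effect)
    if over_candidates is None:
        over_candidates = list(rng.permutation(over_all))
    if under_candidates is None:
        under_candidates = list(rng.permutation([t for t in under_all if t not in set(over_candidates[:k_over])]))
    over_pick = [t for t in over_candidates if t in set(over_all)][:k_over]
    under_pick = [t for t in under_candidates
                  if t in set(under_all) and t not in set(over_pick)][:k_under]
    if len(over_pick) < k_over or len(under_pick) < k_under:
        raise ValueError(
            f"not enough eligible taxa: over {len(over_pick)}/{k_over}, "
            f"under {len(under_pick)}/{k_under}"
        )
    df = table.data.copy()
    S = table.n_samples

    def _fhat_now(t: str) -> float:
        p_now = float((df[t] / df.sum(axis=1)).mean())
        return float(predict_occurrence(np.array([p_now]), m, N)[0])

    # iterate: added/removed detections shift p_i, which shifts the neutral
    # prediction itself, so chase the moving target to a fixed point
    for t in over_pick:
        for _ in range(20):
            detected = int((df[t] > 0).sum())
            target_f = min(1.0, _fhat_now(t) + effect)
            need = int(np.ceil(S * target_f)) - detected
            absent = df.index[df[t] == 0]
            if need <= 0 or len(absent) == 0:
                break
            chosen = rng.choice(absent, size=min(need, len(absent)), replace=False)
            df.loc[chosen, t] = 1
    for t in under_pick:
        # removal reallocates the cleared counts into samples that keep the
        # taxon, so mean abundance (and with it the neutral target) is
        # conserved: present in fewer hosts, more abundant where present
        for _ in range(20):
            detected = int((df[t] > 0).sum())
            target_f = max(0.0, _fhat_now(t) - effect)
            drop = detected - int(np.floor(S * target_f))
            present = list(df.index[df[t] > 0])
            safe = [s for s in present if df.loc[s].sum() > df.at[s, t]]
            if drop <= 0 or len(safe) < 2:
                break
            drop = min(drop, len(safe) - 1)
            chosen = list(rng.choice(safe, size=drop, replace=False))
            keep = [s for s in present if s not in set(chosen)]
            moved = int(df.loc[chosen, t].sum())
            df.loc[chosen, t] = 0
            receivers = rng.choice(keep, size=moved, replace=True)
            uniq, cnt = np.unique(receivers, return_counts=True)
            df.loc[uniq, t] += cnt
    new_truth = replace(
        truth, injected_over=frozenset(over_pick), injected_under=frozenset(under_pick)
    )
    return CountTable(df), new_truth


def _perturb_pool(
    pool: pd.Series, strength: float, rng: np.random.Generator
) -> pd.Series:
    """Displace a pool along a random log-scale direction and renormalize."""
    if strength == 0:
        return pool.copy()
    shift = rng.normal(0.0, strength, size=len(pool))
    logp = np.log(np.clip(pool.to_numpy(), 1e-300, None)) + shift
    logp -= logp.max()
    raw = np.exp(logp)
    raw[pool.to_numpy() == 0] = 0.0
    return pd.Series(raw / raw.sum(), index=pool.index)


def generate_paired_sites(
    n_sites: int = 15,
    polyps_per_site: int = 12,
    gradient_strength: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_taxa: int = 180,
    n_core_taxa: int = 20,
    sigma: float = 2.0,
    m: float = 0.1,
    m_water: float = 0.5,
    depth: int = 10000,
    water_samples_per_site: int = 3,
    host_weight: float = 0.5,
) -> tuple[CountTable, CountTable, SampleMetadata, SyntheticTruth]:
    """Field-survey generator: per-site water pools plus matched host communities.

    Each site's water pool is the global bacterioplankton pool displaced
    along a site-specific log-scale direction scaled by
    ``gradient_strength``; host (polyp) communities assemble neutrally from
    a mixture of a shared host-core community (weight ``host_weight``,
    absent from water) and their site's water pool. ``gradient_strength=0``
    therefore yields site-independent polyps — the null for the
    host-environment distance correlation. Defaults mirror a 15-population
    survey with ~12 polyps and 3 water samples per site.

    Returns (water table, polyp table, metadata, truth); the truth's extras
    carry the per-site pools, the core-taxon ids and the polyp assembly
    pools for recovery tests.
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    if polyps_per_site < 2:
        raise ValueError("polyps_per_site must be >= 2")
    if gradient_strength < 0:
        raise ValueError("gradient_strength must be >= 0")
    rng = np.random.default_rng(seed)
    water_pool = generate_source_pool(n_taxa, sigma, rng, prefix="w")
    core_raw = rng.lognormal(0.0, 1.0, size=n_core_taxa)
    core_pool = pd.Series(core_raw / core_raw.sum(),
                          index=[f"h{i:03d}" for i in range(n_core_taxa)])
    all_taxa = list(water_pool.index) + list(core_pool.index)

    water_frames, polyp_frames, meta_rows = [], [], []
    site_pools: dict[str, pd.Series] = {}
    polyp_pools: dict[str, pd.Series] = {}
    for s in range(n_sites):
        site = f"site{s:02d}"
        site_water = _perturb_pool(water_pool, gradient_strength, rng)
        site_pools[site] = site_water
        # polyp assembly pool: shared host core + this site's water, on the full taxon set
        mix = pd.Series(0.0, index=all_taxa)
        mix[site_water.index] = (1.0 - host_weight) * site_water
        mix[core_pool.index] = host_weight * core_pool
        polyp_pools[site] = mix
        water_mix = pd.Series(0.0, index=all_taxa)
        water_mix[site_water.index] = site_water
        wtab, _ = assemble_neutral_samples(
            water_mix, m_water, depth, water_samples_per_site, rng,
            prefix=f"W_{site}_",
        )
        water_frames.append(wtab.data)
        ptab, _ = assemble_neutral_samples(
            mix, m, depth, polyps_per_site, rng, prefix=f"P_{site}_",
        )
        polyp_frames.append(ptab.data)
        for sid in wtab.sample_ids:
            meta_rows.append((sid, "water", site, site, pd.NA, "none", pd.NA))
        for sid in ptab.sample_ids:
            meta_rows.append((sid, "polyp", site, site, pd.NA, "none", pd.NA))

    water = CountTable(pd.concat(water_frames))
    polyp = CountTable(pd.concat(polyp_frames))
    meta = SampleMetadata(pd.DataFrame(
        meta_rows,
        columns=["sample_id", "sample_type", "population", "site", "timepoint",
                 "treatment", "jar"],
    ))
    truth = SyntheticTruth(
        m=m, depth=depth, source_pool=water_pool,
        gradient_strength=gradient_strength,
        seed=seed if isinstance(seed, int) else None,
        extras={
            "site_water_pools": site_pools,
            "polyp_pools": polyp_pools,
            "core_pool": core_pool,
            "core_taxa": list(core_pool.index),
            "host_weight": host_weight,
        },
    )
    return water, polyp, meta, truth


def _turnover(
    pool: pd.Series, rate: float, rng: np.random.Generator, tag: str, depth: int
) -> tuple[pd.Series, set[str]]:
    """Replace a fraction ``rate`` of rare-taxon identities with novel taxa.

    "Rare" means below the per-sample median relative abundance: the median
    over the taxa a sample of ``depth`` reads actually observes, computed
    here as the detection-probability-weighted median of pool abundances
    (detection probability 1 - exp(-depth * a)).  That cutoff sits a few
    reads above the detection limit, so turnover is visible to
    presence/absence metrics while moving a negligible share of read mass.
    The replacement taxon inherits the replaced taxon's abundance exactly,
    so the sorted abundance vector (dominant structure) is conserved.
    """
    pos = pool[pool > 0].sort_values()
    det = 1.0 - np.exp(-depth * pos.to_numpy())
    cum = np.cumsum(det)
    cutoff = float(pos.to_numpy()[np.searchsorted(cum, 0.5 * cum[-1])])
    rare = list(pos.index[pos < cutoff])
    k = int(round(rate * len(rare)))
    if k == 0:
        return pool.copy(), set()
    replaced = list(rng.choice(rare, size=k, replace=False))
    out = pool.copy()
    novel = set()
    for i, old in enumerate(replaced):
        new_id = f"nov_{tag}_{i:03d}"
        out[new_id] = out[old]
        out[old] = 0.0
        novel.add(new_id)
    return out, novel


def generate_exchange_timeseries(
    n_populations: int = 3,
    jars: int = 5,
    polyps_per_jar: int = 10,
    weeks: int = 4,
    turnover_rate: float = 0.3,
    seed: int | np.random.Generator = 0,
    n_taxa: int = 1000,
    sigma: float = 2.0,
    m: float = 0.1,
    depth: int = 10000,
    population_divergence: float = 1.0,
    lab_shift: float = 0.5,
    common_gain_abundance: float = 0.02,
) -> tuple[CountTable, SampleMetadata, SyntheticTruth]:
    """Water-exchange experiment: native vs foreign culture-water time-series.

    Per population: ``jars`` shared start (week 0, treatment "none") samples,
    then one polyp per jar per week for ``jars`` native and ``jars`` foreign
    jars over ``weeks`` weeks. All week >= 1 samples share a lab-shift (a
    fixed log-scale displacement of the pool, identical in both treatments).
    In the foreign group a fraction ``turnover_rate`` of rare-taxon
    identities (below the pool median) is replaced by novel taxa each week,
    cumulatively, while dominant abundance structure is conserved. One
    designated common-gain taxon ramps up in *all* groups, reaching
    ``common_gain_abundance`` by the final week.

    The truth's extras record every pool, the per-week foreign turnover sets
    and the common-gain taxon id.
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    if not 0 <= turnover_rate < 1:
        raise ValueError("turnover_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    base_pool = generate_source_pool(n_taxa, sigma, rng, prefix="t")
    gain_id = "common_gain"
    lab_dir = rng.normal(0.0, lab_shift, size=n_taxa)

    frames, meta_rows = [], []
    pools: dict[tuple[str, str, int], pd.Series] = {}
    turnover_sets: dict[tuple[str, int], set[str]] = {}

    def with_gain(pool: pd.Series, week: int) -> pd.Series:
        out = pool.copy()
        gain = common_gain_abundance * week / weeks if week >= 1 else 0.0
        out = out * (1.0 - gain)
        out[gain_id] = gain
        return out

    for pidx in range(n_populations):
        pop = f"pop{pidx}"
        pop_pool = _perturb_pool(base_pool, population_divergence, rng)
        shifted = pop_pool.copy()
        if lab_shift > 0:
            logp = np.log(np.clip(pop_pool.to_numpy(), 1e-300, None)) + lab_dir
            raw = np.exp(logp - logp.max())
            raw[pop_pool.to_numpy() == 0] = 0.0
            shifted = pd.Series(raw / raw.sum(), index=pop_pool.index)

        pools[(pop, "none", 0)] = with_gain(pop_pool, 0)
        native_w = {w: with_gain(shifted, w) for w in range(1, weeks + 1)}
        foreign_pool = shifted.copy()
        foreign_w = {}
        for w in range(1, weeks + 1):
            foreign_pool, novel = _turnover(
                foreign_pool, turnover_rate, rng, tag=f"{pop}w{w}", depth=depth
            )
            turnover_sets[(pop, w)] = novel
            foreign_w[w] = with_gain(foreign_pool, w)
        for w in range(1, weeks + 1):
            pools[(pop, "native", w)] = native_w[w]
            pools[(pop, "foreign", w)] = foreign_w[w]

        def emit(pool: pd.Series, treatment: str, week: int, jar_prefix: str) -> None:
            tab, _ = assemble_neutral_samples(
                pool, m, depth, jars, rng,
                prefix=f"{pop}_{treatment}_w{week}_",
            )
            frames.append(tab.data)
            for j, sid in enumerate(tab.sample_ids):
                meta_rows.append((sid, "polyp", pop, pop, week, treatment,
                                  f"{jar_prefix}{j+1}"))

        emit(pools[(pop, "none", 0)], "none", 0, "start")
        for w in range(1, weeks + 1):
            emit(pools[(pop, "native", w)], "native", w, "N")
            emit(pools[(pop, "foreign", w)], "foreign", w, "F")

    data = pd.concat(frames).fillna(0).astype(np.int64)
    table = CountTable(data)
    meta = SampleMetadata(pd.DataFrame(
        meta_rows,
        columns=["sample_id", "sample_type", "population", "site", "timepoint",
                 "treatment", "jar"],
    ))
    truth = SyntheticTruth(
        m=m, depth=depth, source_pool=base_pool,
        gradient_strength=0.0, seed=seed if isinstance(seed, int) else None,
        extras={
            "pools": pools,
            "turnover_sets": turnover_sets,
            "common_gain_taxon": gain_id,
            "turnover_rate": turnover_rate,
            "lab_shift": lab_shift,
        },
    )
    return table, meta, truth
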