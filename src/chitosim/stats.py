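"""Pattern statistics for chitosan populations and digests.

Implements the quantities used to fingerprint the pattern of acetylation:

* fragment DP distributions (molar, or mass-weighted as an RI-signal proxy);
* **triad strength** = (c₃ + c₆) / (c₂ + c₄ + c₅) over DP 2–6 product
  amounts — values > 1 flag an overrepresentation of DP = 3n products;
* composition profiles (counts per (n_A, n_D) product composition);
* number-average A-/D-block sizes, both from a digest profile and directly
  by run-length encoding of the parent chains;
* diad and triad frequencies and the diad-based **PA value**
  PA = (F_AD + F_DA) / (2·F_A·F_D), scaled so 0 = perfectly block-wise,
  1 = perfectly random, 2 = perfectly alternating;
* the closed-form fragment-DP law for complete DA|XX digestion of an
  infinite random chain, used as an analytic oracle for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import A_CODE, D_CODE, M_CODE, ChainPopulation
from .cleavage import FragmentSet

__all__ = [
    "DPDistribution",
    "CompositionProfile",
    "PatternStats",
    "dp_distribution",
    "triad_strength",
    "composition_profile",
    "block_sizes_from_profile",
    "block_sizes_direct",
    "diad_triad_frequencies",
    "pa_value",
    "population_pattern_stats",
    "analytic_aachio_pmf",
    "analytic_aachio_mean_dp",
]

_DIAD_NAMES = ("DD", "DA", "AD", "AA")  # index = 2*first + second (A=1, D=0)
_TRIAD_NAMES = ("DDD", "DDA", "DAD", "DAA", "ADD", "ADA", "AAD", "AAA")


@dataclass
class DPDistribution:
    """Abundance per fragment DP.

    ``counts`` is indexed by DP; ``weighting`` is ``"molar"`` (each fragment
    counted once) or ``"mass"`` (each fragment weighted by its DP, a proxy
    for a refractive-index signal).
    """

    counts: pd.Series
    weighting: str = "molar"

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = self.counts.sort_index()

    @property
    def relative(self) -> pd.Series:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty distribution")
        return self.counts / total

    def get(self, dp: int) -> float:
        return float(self.counts.get(dp, 0.0))


@dataclass
class CompositionProfile:
    """Counts keyed by product composition (n_A, n_D); M counts as D."""

    counts: dict[tuple[int, int], float]

    @property
    def total_products(self) -> float:
        return sum(self.counts.values())

    @property
    def total_units(self) -> float:
        return sum(c * (na + nd) for (na, nd), c in self.counts.items())


@dataclass
class PatternStats:
    """Pooled sequence statistics of a chain population."""

    fa_observed: float
    f_a: float
    f_d: float
    diads: dict[str, float]
    triads: dict[str, float] | None = None
    pa: float | None = None
    mean_a_block: float | None = None
    mean_d_block: float | None = None


def dp_distribution(frag_set: FragmentSet, weighting: str = "molar") -> DPDistribution:
    """DP distribution of a fragment set (molar or mass-weighted)."""
    if weighting not in ("molar", "mass"):
        raise ValueError("weighting must be 'molar' or 'mass'")
    if len(frag_set) == 0:
        raise ValueError("empty fragment set")
    dps = frag_set.dps
    w = dps.astype(float) if weighting == "mass" else None
    counts = np.bincount(dps, weights=w)
    series = pd.Series(counts, index=np.arange(counts.size), dtype=float)
    return DPDistribution(series[series > 0], weighting=weighting)


def triad_strength(dist: DPDistribution | dict) -> float:
    """(c₃ + c₆) / (c₂ + c₄ + c₅) on the distribution's weighting.

    DPs outside 2–6 are ignored; a zero denominator raises rather than
    returning 0 or infinity.
    """
    get = dist.get if isinstance(dist, DPDistribution) else (lambda n: dist.get(n, 0.0))
    num = get(3) + get(6)
    den = get(2) + get(4) + get(5)
    if den == 0:
        raise ValueError("triad strength undefined: no DP 2/4/5 products")
    return num / den


def composition_profile(frag_set: FragmentSet) -> CompositionProfile:
    """Counts per (n_A, n_D) product composition (M counted as D)."""
    if len(frag_set) == 0:
        raise ValueError("empty fragment set")
    counts: dict[tuple[int, int], float] = {}
    for f in frag_set:
        key = (f.n_a, f.n_d)
        counts[key] = counts.get(key, 0.0) + 1.0
    return CompositionProfile(counts)


def block_sizes_from_profile(profile: CompositionProfile) -> tuple[float, float]:
    """Number-average A- and D-block sizes from a DA|XX digest profile.

    Each such product carries exactly one D-block, and its reducing-end A
    plus the next product's leading A-units reassemble one A-block, so the
    mean n_A and mean n_D per product estimate the block sizes up to an
    O(1/DP) chain-end bias.
    """
    n = profile.total_products
    if n == 0:
        raise ValueError("empty composition profile")
    mean_a = sum(c * na for (na, _), c in profile.counts.items()) / n
    mean_d = sum(c * nd for (_, nd), c in profile.counts.items()) / n
    return mean_a, mean_d


def block_sizes_direct(pop: ChainPopulation) -> tuple[float | None, float | None]:
    """Pooled mean A-run and D-run lengths by run-length encoding each chain.

    Serves as the direct oracle for the profile-based estimator. A mean is
    ``None`` when the population has no runs of that unit at all.
    """
    a_total = a_runs = d_total = d_runs = 0
    for chain in pop:
        is_a = np.where(chain.units == M_CODE, D_CODE, chain.units) == A_CODE
        # run starts: position 0 or value change
        starts = np.flatnonzero(np.concatenate(([True], is_a[1:] != is_a[:-1])))
        run_is_a = is_a[starts]
        lengths = np.diff(np.concatenate((starts, [is_a.size])))
        a_total += int(lengths[run_is_a].sum())
        a_runs += int(run_is_a.sum())
        d_total += int(lengths[~run_is_a].sum())
        d_runs += int((~run_is_a).sum())
    mean_a = a_total / a_runs if a_runs else None
    mean_d = d_total / d_runs if d_runs else None
    return mean_a, mean_d


def diad_triad_frequencies(pop: ChainPopulation) -> PatternStats:
    """Pooled diad and triad frequencies across chains.

    Adjacent ordered pairs/triples are counted within each chain (no
    wraparound, no cross-chain pairs) and normalized per category. Chains
    must have DP ≥ 2; triads are reported only if every chain has DP ≥ 3.
    """
    if any(c.dp < 2 for c in pop):
        raise ValueError("diad counting requires every chain to have DP >= 2")
    diad_counts = np.zeros(4, dtype=np.int64)
    triad_counts = np.zeros(8, dtype=np.int64)
    has_triads = all(c.dp >= 3 for c in pop)
    n_a_total = 0
    n_units = 0
    for chain in pop:
        u = np.where(chain.units == M_CODE, D_CODE, chain.units).astype(np.int64)
        n_a_total += int(u.sum())
        n_units += u.size
        diad_counts += np.bincount(2 * u[:-1] + u[1:], minlength=4)
        if has_triads:
            triad_counts += np.bincount(4 * u[:-2] + 2 * u[1:-1] + u[2:], minlength=8)
    f_a = n_a_total / n_units
    diads = dict(zip(_DIAD_NAMES, diad_counts / diad_counts.sum()))
    triads = (
        dict(zip(_TRIAD_NAMES, triad_counts / triad_counts.sum())) if has_triads else None
    )
    return PatternStats(
        fa_observed=f_a, f_a=f_a, f_d=1.0 - f_a, diads=diads, triads=triads
    )


def pa_value(stats: PatternStats) -> float:
    """Diad-based PA value: (F_AD + F_DA) / (2·F_A·F_D).

    Exactly 0 for block-wise populations, 1 in expectation for random ones,
    2 for perfectly alternating chains. Undefined for homopolymers.
    """
    if stats.f_a == 0 or stats.f_d == 0:
        raise ValueError("PA value undefined for a homopolymer population")
    return (stats.diads["AD"] + stats.diads["DA"]) / (2.0 * stats.f_a * stats.f_d)


def population_pattern_stats(pop: ChainPopulation) -> PatternStats:
    """Full pattern statistics: diads, triads, PA value and block sizes."""
    stats = diad_triad_frequencies(pop)
    try:
        stats.pa = pa_value(stats)
    except ValueError:
        stats.pa = None
    stats.mean_a_block, stats.mean_d_block = block_sizes_direct(pop)
    return stats


def analytic_aachio_pmf(fa: float, max_dp: int = 60) -> DPDistribution:
    """Closed-form fragment-DP law for complete DA|XX digestion of an
    infinite random chain with acetylation fraction ``fa``.

    Every interior fragment has the form AˣDʸA (x ≥ 0, y ≥ 1), giving
    P(DP = n) = Σ_{y=1}^{n−1} fa^(n−y)·(1−fa)^y for n ≥ 2; the distribution
    sums to 1 and the mean fragment DP is 1/(fa·(1−fa)).
    """
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must be strictly between 0 and 1")
    q = 1.0 - fa
    ns = np.arange(2, max_dp + 1)
    probs = np.array(
        [sum(fa ** (n - y) * q**y for y in range(1, n)) for n in ns]
    )
    return DPDistribution(pd.Series(probs, index=ns), weighting="molar")


def analytic_aachio_mean_dp(fa: float) -> float:
    """Mean fragment DP of the analytic DA|XX law: 1/(fa·(1−fa))."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must be strictly between 0 and 1")
    return 1.0 / (fa * (1.0 - fa))
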