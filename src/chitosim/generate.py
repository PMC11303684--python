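"""Seeded generators for chitosan chain populations.

The central idea is a position-dependent Bernoulli model of acetylation.
Positions on the every-third-position lattice ("pattern units") are
acetylated with probability ``p_pat``, all other positions with ``p_non``,
with the two probabilities balanced so the expected overall FA equals the
target. The *pattern strength* ``s`` interpolates linearly between the
random case (``s = 0``, every position acetylated with probability FA) and
the strongest admissible lattice bias (``s = 1``, ``p_pat = min(3·FA, 1)``,
which at FA = 1/3 is the ideal (DDA) repeat).

A separate *capped time-course* mode emulates heterogeneous deacetylation
that removes acetyl groups from pattern units only down to a floor: pattern
units keep acetylation probability ``fa_pattern_cap`` while the overall FA
is lowered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chain import A_CODE, ChainPopulation, ChitosanChain

__all__ = [
    "GeneratorParams",
    "acetylation_probabilities",
    "generate_random",
    "generate_patterned",
    "generate_capped_timecourse",
    "population_summary",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of a chain-population generator run.

    Parameters
    ----------
    n_chains
        Number of molecules to generate.
    dp
        Degree of polymerization of every chain.
    fa
        Target fraction of acetylation in [0, 1] (expected value; individual
        chains vary binomially).
    s
        Pattern strength in [0, 1]: 0 = random PA, 1 = strongest
        overrepresentation of A-units at every third position.
    fa_pattern_cap
        If set, switches to the capped time-course mode: pattern units are
        acetylated with exactly this probability regardless of ``s``.
    phase_mode
        ``"random"`` draws the lattice phase r ∈ {0, 1, 2} uniformly per
        chain; ``"fixed:r"`` pins it (deterministic fixtures).
    seed
        Seed of the numpy PRNG stream; identical params + seed reproduce the
        population bit-exactly.
    """

    n_chains: int
    dp: int
    fa: float
    s: float = 0.0
    fa_pattern_cap: float | None = None
    phase_mode: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError("fa must be in [0, 1]")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("pattern strength s must be in [0, 1]")
        self._parse_phase()
        if self.fa_pattern_cap is not None:
            if not 0.0 <= self.fa_pattern_cap <= 1.0:
                raise ValueError("fa_pattern_cap must be in [0, 1]")

    def _parse_phase(self) -> int | None:
        """Return the fixed phase, or None for a random phase per chain."""
        if self.phase_mode == "random":
            return None
        if self.phase_mode.startswith("fixed:"):
            r = int(self.phase_mode.split(":", 1)[1])
            if r not in (0, 1, 2):
                raise ValueError("fixed phase must be 0, 1 or 2")
            return r
        raise ValueError(f"unknown phase_mode {self.phase_mode!r}")


def acetylation_probabilities(fa: float, s: float) -> tuple[float, float]:
    """Per-position acetylation probabilities (p_pat, p_non) for given FA and s.

    ``p_pat`` applies to pattern units (every third position), ``p_non`` to
    the rest. Linear interpolation: ``p_pat = fa + s·(min(3·fa, 1) − fa)``,
    with ``p_non = (3·fa − p_pat)/2`` so that ``p_pat + 2·p_non = 3·fa``
    and the expected FA equals ``fa`` whenever DP is divisible by 3.

    >>> acetylation_probabilities(0.32, 0.0)
    (0.32, 0.32)
    >>> acetylation_probabilities(1/3, 1.0)
    (1.0, 0.0)
    """
    if not 0.0 <= fa <= 1.0:
        raise ValueError("fa must be in [0, 1]")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    p_pat = fa + s * (min(3.0 * fa, 1.0) - fa)
    p_non = (3.0 * fa - p_pat) / 2.0
    for name, p in (("p_pat", p_pat), ("p_non", p_non)):
        if not -1e-12 <= p <= 1.0 + 1e-12:
            raise ValueError(f"derived {name}={p} outside [0, 1]")
    return min(max(p_pat, 0.0), 1.0), min(max(p_non, 0.0), 1.0)


def _generate(params: GeneratorParams, p_pat: float, p_non: float, mode: str) -> ChainPopulation:
    rng = np.random.default_rng(params.seed)
    fixed_phase = params._parse_phase()
    chains: list[ChitosanChain] = []
    positions = np.arange(1, params.dp + 1)  # 1-based
    for i in range(params.n_chains):
        r = int(rng.integers(3)) if fixed_phase is None else fixed_phase
        probs = np.where((positions - r) % 3 == 0, p_pat, p_non)
        units = (rng.random(params.dp) < probs).astype(np.uint8) * A_CODE
        chains.append(ChitosanChain(units, id=f"chain_{i}"))
    meta = {
        "mode": mode,
        "n_chains": params.n_chains,
        "dp": params.dp,
        "fa": params.fa,
        "s": params.s,
        "fa_pattern_cap": params.fa_pattern_cap,
        "phase_mode": params.phase_mode,
        "seed": params.seed,
        "p_pat": p_pat,
        "p_non": p_non,
    }
    return ChainPopulation(chains, metadata=meta)


def generate_patterned(params: GeneratorParams) -> ChainPopulation:
    """Generate chains with A-units overrepresented at every third position.

    Per chain a lattice phase r is chosen (see ``phase_mode``); positions i
    with (i − r) mod 3 = 0 are pattern units acetylated with probability
    ``p_pat``, all others with ``p_non``. At ``s = 0`` this reduces exactly
    to the random generator (same PRNG stream, same output).
    """
    p_pat, p_non = acetylation_probabilities(params.fa, params.s)
    return _generate(params, p_pat, p_non, mode="patterned" if params.s > 0 else "random")


def generate_random(params: GeneratorParams) -> ChainPopulation:
    """Generate completely random-PA chains (each unit A with probability fa).

    Requires ``s = 0``; delegates to :func:`generate_patterned` so both
    generators share one PRNG policy and produce identical output at s = 0.
    """
    if params.s != 0.0:
        raise ValueError("generate_random requires s = 0")
    return generate_patterned(params)


def generate_capped_timecourse(params: GeneratorParams) -> ChainPopulation:
    """Generate chains emulating a deacetylation time course with protected
    pattern units.

    Pattern units stay acetylated with probability ``fa_pattern_cap`` while
    non-pattern units carry ``(3·fa − cap)/2`` so the overall FA hits the
    target. Feasible only for ``0 ≤ 3·fa − cap ≤ 2``.
    """
    cap = params.fa_pattern_cap
    if cap is None:
        raise ValueError("fa_pattern_cap must be set for the time-course mode")
    p_non = (3.0 * params.fa - cap) / 2.0
    if not 0.0 <= p_non <= 1.0:
        raise ValueError(
            f"infeasible (fa={params.fa}, cap={cap}): non-pattern probability "
            f"{p_non:.4f} outside [0, 1]"
        )
    return _generate(params, cap, p_non, mode="capped_timecourse")


def population_summary(pop: ChainPopulation) -> dict:
    """Observed FA, per-chain FA spread (a proxy for FA dispersity), and DPs."""
    per_chain_fa = np.array([c.fa for c in pop.chains])
    dps = [c.dp for c in pop.chains]
    return {
        "n_chains": pop.n_chains,
        "total_units": pop.total_units,
        "fa_observed": pop.fa_observed,
        "per_chain_fa_mean": float(per_chain_fa.mean()),
        "per_chain_fa_var": float(per_chain_fa.var()),
        "dp_min": min(dps),
        "dp_max": max(dps),
        "dp_mean": float(np.mean(dps)),
    }
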