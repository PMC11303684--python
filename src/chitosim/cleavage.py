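"""Subsite-specific cleavage of chitosan chains.

A cleavage agent (enzyme or chemical) is described by its requirements at
the four subsites flanking the scissile glycosidic bond: −2 and −1 on the
non-reducing side, +1 and +2 on the reducing side. Each requirement is
``A`` (the subsite must hold an A-unit), ``D`` (a D-unit) or ``X`` (no
requirement). Site k is the bond between units k and k+1 (1 ≤ k ≤ DP−1);
the subsites map to unit positions k−1, k, k+1, k+2.

Presets cover the agents commonly used for chitosan fingerprinting:

========  =========  =============================================
name      spec       behaviour
========  =========  =============================================
AaChio    ``DA|XX``  chitinosanase, cuts after each D→A motif
CsnMN     ``DD|XX``  chitosanase (simplified absolute specificity)
GH18      ``XA|XX``  chitinase, cuts after A-units
GH19      ``AX|AX``  chitinase requiring A at −2 and +1
TFA       ``XA|XX``  acid hydrolysis after A-units (simplified)
HNO2      ``XD|XX``  nitrous acid, cuts after D-units and converts
                     the −1 D-unit to 2,5-anhydro-D-mannose (M)
========  =========  =============================================

Partial cleavage is modeled as an independent Bernoulli(q) decision per
eligible site; ``q = 1`` is a complete end-point digestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chain import A_CODE, D_CODE, M_CODE, ChainPopulation, ChitosanChain, decode

__all__ = [
    "CleavageSpec",
    "Fragment",
    "FragmentSet",
    "PRESETS",
    "parse_spec",
    "get_spec",
    "find_sites",
    "cleave_chain",
    "digest_population",
]

_REQ_CODES = {"A": A_CODE, "D": D_CODE}


@dataclass(frozen=True)
class CleavageSpec:
    """Subsite requirements of a cleavage agent.

    ``requirements`` is the 4-tuple for subsites (−2, −1, +1, +2), each
    ``"A"``, ``"D"`` or ``"X"``; ``q`` is the per-site cleavage
    probability; ``deaminating`` marks the −1 unit of each realized cut as
    M in the product (nitrous acid only).
    """

    name: str
    requirements: tuple[str, str, str, str]
    q: float = 1.0
    deaminating: bool = False

    def __post_init__(self) -> None:
        if len(self.requirements) != 4 or any(
            r not in ("A", "D", "X") for r in self.requirements
        ):
            raise ValueError("requirements must be a 4-tuple over {A, D, X}")
        if all(r == "X" for r in self.requirements):
            raise ValueError("at least one subsite requirement must be non-X")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must be in (0, 1]")

    @property
    def text(self) -> str:
        r = self.requirements
        return f"{r[0]}{r[1]}|{r[2]}{r[3]}"

    def with_q(self, q: float) -> "CleavageSpec":
        return replace(self, q=q)


def parse_spec(
    text: str, name: str | None = None, q: float = 1.0, deaminating: bool = False
) -> CleavageSpec:
    """Parse a ``"LL|RR"`` specificity string (L, R ∈ {A, D, X}).

    >>> parse_spec("DA|XX").requirements
    ('D', 'A', 'X', 'X')
    """
    if len(text) != 5 or text[2] != "|":
        raise ValueError(f"spec string must be 'LL|RR' with '|' in the middle, got {text!r}")
    reqs = (text[0], text[1], text[3], text[4])
    return CleavageSpec(name or text, reqs, q=q, deaminating=deaminating)


#: Preset specificities (simplified absolute subsite requirements).
PRESETS: dict[str, CleavageSpec] = {
    "AaChio": parse_spec("DA|XX", name="AaChio"),
    "CsnMN": parse_spec("DD|XX", name="CsnMN"),
    "GH18": parse_spec("XA|XX", name="GH18"),
    "GH19": parse_spec("AX|AX", name="GH19"),
    "TFA": parse_spec("XA|XX", name="TFA"),
    "HNO2": parse_spec("XD|XX", name="HNO2", deaminating=True),
}


def get_spec(name_or_text: str, q: float | None = None) -> CleavageSpec:
    """Resolve a preset name or a raw ``LL|RR`` string, optionally setting q."""
    spec = PRESETS.get(name_or_text) or parse_spec(name_or_text)
    if q is not None:
        spec = spec.with_q(q)
    return spec


@dataclass
class Fragment:
    """A cleavage product with provenance (parent chain and coordinates).

    ``start``/``end`` are 1-based inclusive positions in the parent.
    """

    units: np.ndarray
    parent_id: str = ""
    start: int = 1
    end: int = 0

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.uint8)
        if self.end == 0:
            self.end = self.start + self.units.size - 1

    @property
    def dp(self) -> int:
        return int(self.units.size)

    @property
    def sequence(self) -> str:
        return decode(self.units)

    @property
    def n_a(self) -> int:
        return int(np.count_nonzero(self.units == A_CODE))

    @property
    def n_d(self) -> int:
        """D-unit count; the deaminated M unit counts as D."""
        return self.dp - self.n_a


@dataclass
class FragmentSet:
    """All products of digesting a population, with bond bookkeeping."""

    fragments: list[Fragment]
    n_bonds_total: int
    n_bonds_cut: int

    @property
    def cleavage_fraction(self) -> float:
        return self.n_bonds_cut / self.n_bonds_total if self.n_bonds_total else 0.0

    @property
    def dps(self) -> np.ndarray:
        return np.array([f.dp for f in self.fragments], dtype=np.int64)

    @property
    def total_units(self) -> int:
        return int(self.dps.sum())

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


def find_sites(chain: ChitosanChain, spec: CleavageSpec) -> np.ndarray:
    """Eligible cleavage sites k (bond between units k and k+1, 1-based).

    A site is eligible iff every non-X requirement matches the unit at its
    mapped position AND that position lies inside the chain: the agent must
    bind a real sugar at every required subsite, so a non-X requirement
    falling off a chain end disables the site. Evaluated on the intact chain.
    """
    u = chain.units
    n = u.size
    if n < 2:
        return np.empty(0, dtype=np.int64)
    k = np.arange(1, n, dtype=np.int64)
    ok = np.ones(n - 1, dtype=bool)
    # subsites (−2, −1, +1, +2) sit at unit positions k−1, k, k+1, k+2
    for offset, req in zip((-1, 0, 1, 2), spec.requirements):
        if req == "X":
            continue
        pos = k + offset  # 1-based unit position
        inside = (pos >= 1) & (pos <= n)
        match = np.zeros(n - 1, dtype=bool)
        idx = pos[inside] - 1
        match[inside] = u[idx] == _REQ_CODES[req]
        ok &= match
    return k[ok]


def _split(chain: ChitosanChain, cuts: np.ndarray, deaminating: bool) -> list[Fragment]:
    bounds = np.concatenate(([0], np.sort(cuts), [chain.dp]))
    frags = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        units = chain.units[a:b].copy()
        if deaminating and b != chain.dp:  # reducing end created by a cut
            units[-1] = M_CODE
        frags.append(Fragment(units, parent_id=chain.id, start=int(a) + 1, end=int(b)))
    return frags


def cleave_chain(
    chain: ChitosanChain,
    spec: CleavageSpec,
    rng: np.random.Generator | None = None,
    mode: str = "endpoint",
) -> list[Fragment]:
    """Cleave one chain; returns fragments in non-reducing → reducing order.

    ``mode="endpoint"`` (default) evaluates eligibility once on the intact
    chain and cuts all realized sites simultaneously. ``mode="iterative"``
    cuts one randomly chosen eligible site at a time and re-evaluates
    eligibility within the resulting fragments, so a −2/+2 requirement lost
    to a prior cut disables a site.
    """
    if spec.q < 1.0 and rng is None:
        raise ValueError("partial cleavage (q < 1) requires an rng")
    if mode == "endpoint":
        sites = find_sites(chain, spec)
        if spec.q < 1.0 and sites.size:
            sites = sites[rng.random(sites.size) < spec.q]
        return _split(chain, sites, spec.deaminating)
    if mode == "iterative":
        if rng is None:
            rng = np.random.default_rng(0)
        done: list[Fragment] = []
        stack = [Fragment(chain.units.copy(), parent_id=chain.id, start=1, end=chain.dp)]
        while stack:
            frag = stack.pop()
            sub = ChitosanChain(np.where(frag.units == M_CODE, D_CODE, frag.units))
            sites = find_sites(sub, spec)
            if spec.q < 1.0 and sites.size:
                sites = sites[rng.random(sites.size) < spec.q]
            if sites.size == 0:
                done.append(frag)
                continue
            k = int(rng.choice(sites))
            left = frag.units[:k].copy()
            if spec.deaminating:
                left[-1] = M_CODE
            stack.append(Fragment(frag.units[k:], frag.parent_id, frag.start + k, frag.end))
            stack.append(Fragment(left, frag.parent_id, frag.start, frag.start + k - 1))
        done.sort(key=lambda f: f.start)
        return done
    raise ValueError(f"unknown mode {mode!r}")


def digest_population(
    pop: ChainPopulation,
    spec: CleavageSpec,
    seed: int | None = 0,
    mode: str = "endpoint",
) -> FragmentSet:
    """Digest every chain in a population; conserves the total unit count."""
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    n_bonds_total = 0
    n_bonds_cut = 0
    for chain in pop:
        frags = cleave_chain(chain, spec, rng=rng, mode=mode)
        fragments.extend(frags)
        n_bonds_total += chain.dp - 1
        n_bonds_cut += len(frags) - 1
    return FragmentSet(fragments, n_bonds_total, n_bonds_cut)
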