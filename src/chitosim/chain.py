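"""Chitosan chains as sequences over the {A, D} alphabet.

A chain is an ordered sequence of sugar units read from the non-reducing
end (position 1) to the reducing end (position DP):

* ``A`` — N-acetyl-D-glucosamine (GlcNAc), the acetylated unit;
* ``D`` — D-glucosamine (GlcN), the deacetylated unit;
* ``M`` — 2,5-anhydro-D-mannose, produced from a D-unit by nitrous-acid
  deamination. ``M`` may occur only at the reducing end of a fragment and
  counts as a D-unit in all composition statistics.

Units are stored as small unsigned integer codes in a numpy array; the
string view is available via :attr:`ChitosanChain.sequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Integer codes for the three unit types.
D_CODE: int = 0
A_CODE: int = 1
M_CODE: int = 2

_CHAR_TO_CODE = {"D": D_CODE, "A": A_CODE, "M": M_CODE}
_CODE_TO_CHAR = np.array(["D", "A", "M"])


def encode(sequence: str) -> np.ndarray:
    """Encode a string over {A, D, M} into unit codes."""
    try:
        return np.array([_CHAR_TO_CODE[c] for c in sequence], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"invalid unit {exc.args[0]!r}; alphabet is A/D/M") from exc


def decode(units: np.ndarray) -> str:
    """Decode unit codes back into a string over {A, D, M}."""
    return "".join(_CODE_TO_CHAR[np.asarray(units, dtype=np.uint8)])


@dataclass
class ChitosanChain:
    """A single chitosan molecule.

    Parameters
    ----------
    units
        Unit codes (``uint8``), position 1 = non-reducing end.
    id
        Optional identifier (used in FASTA output and fragment provenance).
    """

    units: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.uint8)
        if self.units.ndim != 1 or self.units.size < 1:
            raise ValueError("a chain needs at least one unit")
        if self.units.max(initial=0) > M_CODE:
            raise ValueError("unit codes must be in {0 (D), 1 (A), 2 (M)}")
        m_positions = np.flatnonzero(self.units == M_CODE)
        if m_positions.size and (m_positions.size > 1 or m_positions[0] != self.units.size - 1):
            raise ValueError("M (deaminated unit) may appear only at the reducing end")

    @classmethod
    def from_string(cls, sequence: str, id: str = "") -> "ChitosanChain":
        return cls(encode(sequence), id=id)

    @property
    def dp(self) -> int:
        """Degree of polymerization (chain length in sugar units)."""
        return int(self.units.size)

    @property
    def sequence(self) -> str:
        return decode(self.units)

    @property
    def n_a(self) -> int:
        """Number of A-units."""
        return int(np.count_nonzero(self.units == A_CODE))

    @property
    def n_d(self) -> int:
        """Number of D-units (M counts as D)."""
        return self.dp - self.n_a

    @property
    def fa(self) -> float:
        """Fraction of acetylation of this single chain."""
        return self.n_a / self.dp

    def __len__(self) -> int:
        return self.dp

    def __repr__(self) -> str:
        seq = self.sequence
        if len(seq) > 40:
            seq = seq[:37] + "..."
        return f"ChitosanChain(dp={self.dp}, {seq!r})"


@dataclass
class ChainPopulation:
    """A population of chitosan chains plus the parameters that produced it.

    ``metadata`` records every generator parameter needed to regenerate the
    population bit-exactly (mode, n_chains, dp, fa, s, cap, phase_mode, seed).
    """

    chains: list[ChitosanChain]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a population must contain at least one chain")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def total_units(self) -> int:
        return sum(c.dp for c in self.chains)

    @property
    def fa_observed(self) -> float:
        """Pooled fraction of acetylation: A-units / all units."""
        return sum(c.n_a for c in self.chains) / self.total_units

    def __iter__(self) -> Iterator[ChitosanChain]:
        return iter(self.chains)

    def __len__(self) -> int:
        return self.n_chains


def make_ideal_repeat(motif: str, dp: int, id: str = "") -> ChitosanChain:
    """Build a chain by cyclically repeating ``motif`` and truncating to ``dp``.

    Useful for deterministic fixtures such as the ideal (DDA) repeat, the
    perfectly alternating (AD) polymer, or homopolymer blocks.

    >>> make_ideal_repeat("DDA", 9).sequence
    'DDADDADDA'
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if dp < 1:
        raise ValueError("dp must be >= 1")
    if any(c not in ("A", "D") for c in motif):
        raise ValueError("motif alphabet is {A, D}")
    codes = encode(motif)
    reps = int(np.ceil(dp / codes.size))
    return ChitosanChain(np.tile(codes, reps)[:dp], id=id)
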