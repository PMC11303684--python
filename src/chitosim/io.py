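"""FASTA / TSV / JSON serialization of populations, fragments and statistics.

Chain populations round-trip through FASTA (one record per chain, sequence
over {A, D, M}); generator metadata travels as ``key=value`` tokens in the
record description. Fragment sets round-trip through TSV with the bond
bookkeeping stored in ``#``-prefixed header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chain import ChainPopulation, ChitosanChain
from .cleavage import Fragment, FragmentSet

_META_KEYS = ("mode", "n_chains", "dp", "fa", "s", "fa_pattern_cap", "phase_mode", "seed")


def write_population_fasta(pop: ChainPopulation, path: str | Path) -> None:
    """Write a population as FASTA with metadata in the record descriptions."""
    desc = " ".join(
        f"{k}={pop.metadata[k]}" for k in _META_KEYS if pop.metadata.get(k) is not None
    )
    records = [
        SeqRecord(Seq(c.sequence), id=c.id or f"chain_{i}", description=desc)
        for i, c in enumerate(pop)
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_token(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def read_population_fasta(path: str | Path) -> ChainPopulation:
    """Read a population from FASTA; metadata is recovered from the headers."""
    chains = []
    metadata: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chains.append(ChitosanChain.from_string(str(rec.seq), id=rec.id))
        if not metadata:
            for token in rec.description.split()[1:]:
                if "=" in token:
                    k, v = token.split("=", 1)
                    metadata[k] = _parse_token(v)
    return ChainPopulation(chains, metadata=metadata)


def write_fragments_tsv(frag_set: FragmentSet, path: str | Path) -> None:
    """Write fragments as TSV (parent_id, start, end, dp, n_A, n_D, sequence)."""
    rows = [
        (f.parent_id, f.start, f.end, f.dp, f.n_a, f.n_d, f.sequence)
        for f in frag_set
    ]
    df = pd.DataFrame(rows, columns=["parent_id", "start", "end", "dp", "n_A", "n_D", "sequence"])
    with open(path, "w") as fh:
        fh.write(f"# n_bonds_total={frag_set.n_bonds_total}\n")
        fh.write(f"# n_bonds_cut={frag_set.n_bonds_cut}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> FragmentSet:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, v = line[1:].strip().split("=", 1)
            meta[k.strip()] = int(v)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    fragments = [
        Fragment(
            ChitosanChain.from_string(r.sequence).units,
            parent_id=str(r.parent_id),
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.itertuples()
    ]
    return FragmentSet(
        fragments,
        n_bonds_total=meta.get("n_bonds_total", sum(f.dp for f in fragments) - 1),
        n_bonds_cut=meta.get("n_bonds_cut", len(fragments) - 1),
    )


def write_json(obj: dict, path: str | Path | None) -> str:
    """Serialize a summary dict; write to ``path`` if given, return the text."""
    text = json.dumps(obj, indent=2, default=float)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
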