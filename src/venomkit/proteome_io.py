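"""Proteome FASTA I/O, gene/protein id mapping, and longest-isoform filtering.

Orthology clustering across species proteomes is conventionally run on one
representative protein per gene; the representative used here is the longest
isoform, with deterministic tie-breaking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from venomkit.errors import ValidationError

#: protein ids like "g123.t2" or "g123.p1" map to gene "g123"
_ISOFORM_SUFFIX = re.compile(r"\.[tp]\d+$")

IdParser = Callable[[str], tuple[str, str]]


def default_id_parser(header: str) -> tuple[str, str]:
    """Parse a FASTA header into (protein_id, gene_id).

    The first whitespace-delimited token is the protein id; the gene id is
    derived by stripping a trailing isoform suffix (".t<N>" or ".p<N>").
    A protein id without such a suffix is its own gene id.
    """
    protein_id = header.split()[0]
    gene_id = _ISOFORM_SUFFIX.sub("", protein_id)
    return protein_id, gene_id


def make_regex_parser(pattern: str) -> IdParser:
    """Build a header parser from a regex with named groups.

    `pattern` must define a ``protein`` group and may define a ``gene``
    group; if ``gene`` is absent the protein id doubles as the gene id.
    """
    rx = re.compile(pattern)

    def parse(header: str) -> tuple[str, str]:
        m = rx.search(header)
        if m is None:
            raise ValidationError(
                f"header {header!r} does not match id pattern {pattern!r}"
            )
        protein_id = m.group("protein")
        gene_id = m.group("gene") if "gene" in rx.groupindex else protein_id
        return protein_id, gene_id

    return parse


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species and gene assignment."""

    protein_id: str
    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        if not self.gene_id:
            raise ValidationError(f"protein {self.protein_id!r}: empty gene_id")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """An ordered collection of protein records for one species."""

    species_id: str
    records: list[ProteinRecord] = field(default_factory=list)
    isoform_filtered: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]

    def gene_map(self) -> dict[str, str]:
        """protein_id -> gene_id over all records."""
        return {r.protein_id: r.gene_id for r in self.records}


def read_fasta(
    path: str | Path,
    species_id: str,
    id_parser: IdParser = default_id_parser,
) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Multi-line sequences are concatenated; entry order is preserved.
    Raises :class:`ValidationError` on duplicate protein ids or empty
    sequences, naming the offending entry.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        protein_id, gene_id = id_parser(entry.description or entry.id)
        if protein_id in seen:
            raise ValidationError(
                f"duplicate protein id {protein_id!r} in {path}"
            )
        seen.add(protein_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                gene_id=gene_id,
                species_id=species_id,
                sequence=str(entry.seq).upper(),
            )
        )
    return Proteome(species_id=species_id, records=records)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome to FASTA with `width`-column wrapped sequences."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in proteome.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(entries)


def longest_isoform_filter(proteome: Proteome) -> Proteome:
    """Keep the single longest isoform per gene.

    Length ties are broken toward the lexicographically smallest protein id
    so the choice is deterministic. Idempotent; output order follows the
    first occurrence of each gene in the input.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in proteome.records:
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif (len(rec), _neg_lex(rec.protein_id)) > (len(cur), _neg_lex(cur.protein_id)):
            best[rec.gene_id] = rec
    return Proteome(
        species_id=proteome.species_id,
        records=[best[g] for g in order],
        isoform_filtered=True,
    )


class _neg_lex(str):
    """Reverses string comparison so max() prefers the smaller id on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
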