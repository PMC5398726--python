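"""Domain-annotation filtering and gene-family venom-coverage statistics.

Given profile-HMM domain hits over a whole proteome and the set of secreted
(venom) proteins, computes, per domain family, how many genes in the genome
encode the domain and what share of the family is detected in the venom.
Hits are first filtered at a stringent E-value threshold (1e-6 by default).

Note the deliberate asymmetry of the coverage statistic: the denominator
counts distinct *genes* whose products carry the domain, while the numerator
counts venom *proteins* carrying it — the convention of published venom
family-coverage tables. A flag forces gene-level counting on both sides.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from venomkit.errors import ValidationError

_VERSION_SUFFIX = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_accession: str
    domain_name: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(
                f"negative E-value for {self.protein_id}/{self.domain_accession}"
            )


@dataclass(frozen=True)
class FamilyCoverage:
    domain_accession: str
    domain_name: str
    n_genome: int
    n_venom: int
    pct_in_venom: int


def strip_version(accession: str) -> str:
    """Drop a trailing Pfam version suffix ('.2' in 'PF12714.2')."""
    return _VERSION_SUFFIX.sub("", accession)


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def filter_hits(
    hits: Sequence[DomainHit], e_max: float = 1e-6
) -> list[DomainHit]:
    """Keep hits with E-value <= e_max; preserves input order."""
    return [h for h in hits if h.e_value <= e_max]


def family_coverage(
    genome_hits: Sequence[DomainHit],
    venom_ids: Iterable[str],
    gene_map: Mapping[str, str],
    gene_level_venom: bool = False,
) -> list[FamilyCoverage]:
    """Per-domain family coverage of the venom over the genome.

    ``n_genome`` counts distinct genes with at least one hit for the domain;
    ``n_venom`` counts distinct venom proteins with a hit (or distinct venom
    genes when ``gene_level_venom``); the percentage is round-half-up of
    100 * n_venom / n_genome. Families are returned sorted by descending
    percentage, then accession.
    """
    venom = set(venom_ids)
    missing = sorted(venom - set(gene_map))
    if missing:
        raise ValidationError(
            f"venom ids absent from the gene map: {missing[:5]}"
        )

    genes: dict[str, set[str]] = {}
    venom_hits: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for h in genome_hits:
        acc = strip_version(h.domain_accession)
        names.setdefault(acc, h.domain_name)
        if h.protein_id not in gene_map:
            raise ValidationError(
                f"hit protein {h.protein_id!r} absent from the gene map"
            )
        genes.setdefault(acc, set()).add(gene_map[h.protein_id])
        if h.protein_id in venom:
            key = gene_map[h.protein_id] if gene_level_venom else h.protein_id
            venom_hits.setdefault(acc, set()).add(key)

    out = [
        FamilyCoverage(
            domain_accession=acc,
            domain_name=names[acc],
            n_genome=len(genes[acc]),
            n_venom=len(venom_hits.get(acc, ())),
            pct_in_venom=round_half_up(
                100.0 * len(venom_hits.get(acc, ())) / len(genes[acc])
            ),
        )
        for acc in genes
    ]
    out.sort(key=lambda c: (-c.pct_in_venom, c.domain_accession))
    return out


# ---------------------------------------------------------------------------
# input dialects

def read_domain_tsv(path: str | Path) -> list[DomainHit]:
    """Simplified TSV: protein_id, domain_accession, domain_name, e_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_accession", "domain_name", "e_value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"domain table needs columns {sorted(required)}")
    return [
        DomainHit(r.protein_id, r.domain_accession, r.domain_name, float(r.e_value))
        for r in df.itertuples(index=False)
    ]


def read_domtbl(path: str | Path) -> list[DomainHit]:
    """Parse hmmscan/hmmsearch --domtblout (per-domain table).

    Uses the full-sequence E-value (column 7). Assumes the scan queried
    proteins against a domain database, i.e. target = domain, query =
    protein (hmmscan orientation).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 13:
                raise ValidationError(f"{path}:{lineno}: truncated domtbl row")
            domain_name, domain_acc, _, protein_id = parts[0], parts[1], parts[2], parts[3]
            e_value = float(parts[6])
            hits.append(DomainHit(protein_id, domain_acc, domain_name, e_value))
    return hits


def coverage_frame(coverages: Sequence[FamilyCoverage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "domain_name": [c.domain_name for c in coverages],
            "domain_accession": [c.domain_accession for c in coverages],
            "n_genome": [c.n_genome for c in coverages],
            "n_venom": [c.n_venom for c in coverages],
            "pct_in_venom": [c.pct_in_venom for c in coverages],
        }
    )
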