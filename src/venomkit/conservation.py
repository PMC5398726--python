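"""Orthology-cluster parsing and venom-protein conservation analysis.

Venom proteins of the focal species are placed in one of three mutually
exclusive conservation categories based on the species composition of the
orthology cluster they belong to:

* ``distant_conserved`` — the cluster contains at least one protein from a
  distantly related (here, vertebrate-parasitic) nematode;
* ``sister_conserved`` — no distant member, but at least one protein from a
  congeneric sister species;
* ``focal_specific`` — neither; the protein is specific to the focal species.

The precedence distant > sister > specific makes the categories a partition.
Species outside both comparison groups (an ``other`` set) never promote a
cluster out of ``focal_specific``. Combining categories with emPAI molar
fractions yields the share of venom *molecules* per category and a ranking
of clusters by their contribution to the secretion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from venomkit.empai import EmpaiRecord
from venomkit.errors import ParseError, ValidationError


class ConservationCategory(str, Enum):
    DISTANT_CONSERVED = "distant_conserved"
    SISTER_CONSERVED = "sister_conserved"
    FOCAL_SPECIFIC = "focal_specific"


@dataclass(frozen=True)
class SpeciesGroups:
    """Partition of the comparison species into conservation groups."""

    focal: str
    sister_group: frozenset[str] = frozenset()
    distant_group: frozenset[str] = frozenset()
    other: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        groups = [self.sister_group, self.distant_group, self.other]
        seen: set[str] = set()
        for g in groups:
            overlap = seen & set(g)
            if overlap:
                raise ValidationError(
                    f"species in more than one group: {sorted(overlap)}"
                )
            seen |= set(g)
        if self.focal in seen:
            raise ValidationError(f"focal species {self.focal!r} also in a group")

    @property
    def all_species(self) -> frozenset[str]:
        return frozenset({self.focal}) | self.sister_group | self.distant_group | self.other

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesGroups":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            focal=raw["focal"],
            sister_group=frozenset(raw.get("sister_group", [])),
            distant_group=frozenset(raw.get("distant_group", [])),
            other=frozenset(raw.get("other", [])),
        )


@dataclass
class OrthologyClusterSet:
    """cluster_id -> ordered list of (species_id, protein_id) members."""

    clusters: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    provenance: str = ""

    def membership(self) -> dict[tuple[str, str], str]:
        """(species, protein) -> cluster_id; proteins belong to one cluster."""
        out: dict[tuple[str, str], str] = {}
        for cid, members in self.clusters.items():
            for m in members:
                if m in out:
                    raise ValidationError(
                        f"protein {m[1]!r} ({m[0]}) in clusters "
                        f"{out[m]!r} and {cid!r}"
                    )
                out[m] = cid
        return out

    def n_members(self) -> int:
        return sum(len(v) for v in self.clusters.values())


def parse_groups(
    path: str | Path,
    id_separator: str = "|",
    known_species: Iterable[str] | None = None,
) -> OrthologyClusterSet:
    """Parse an OrthoMCL-style groups file.

    Each non-empty line reads ``cluster_id: sp<sep>prot sp<sep>prot ...``.
    Raises :class:`ParseError` with the line number on malformed lines and
    :class:`ValidationError` on unknown species (when ``known_species`` is
    given) or on a protein assigned to two clusters.
    """
    known = set(known_species) if known_species is not None else None
    clusters: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: missing 'cluster_id:' prefix")
            cid, _, rest = line.partition(":")
            cid = cid.strip()
            if not cid:
                raise ParseError(f"{path}:{lineno}: empty cluster id")
            if cid in clusters:
                raise ParseError(f"{path}:{lineno}: duplicate cluster id {cid!r}")
            members: list[tuple[str, str]] = []
            for tok in rest.split():
                if id_separator not in tok:
                    raise ParseError(
                        f"{path}:{lineno}: member {tok!r} lacks separator "
                        f"{id_separator!r}"
                    )
                sp, _, prot = tok.partition(id_separator)
                if not sp or not prot:
                    raise ParseError(f"{path}:{lineno}: malformed member {tok!r}")
                if known is not None and sp not in known:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown species {sp!r}"
                    )
                members.append((sp, prot))
            clusters[cid] = members
    out = OrthologyClusterSet(clusters=clusters, provenance=str(path))
    out.membership()  # raises if a protein is in two clusters
    return out


def write_groups(
    clusters: OrthologyClusterSet, path: str | Path, id_separator: str = "|"
) -> None:
    with open(path, "w") as fh:
        for cid, members in clusters.clusters.items():
            toks = " ".join(f"{sp}{id_separator}{prot}" for sp, prot in members)
            fh.write(f"{cid}: {toks}\n")


def augment_singletons(
    clusters: OrthologyClusterSet,
    venom_ids: Iterable[str],
    focal_species: str,
    prefix: str = "singleton",
) -> OrthologyClusterSet:
    """Give every unclustered venom protein its own singleton cluster.

    Makes the cluster partition exhaustive over the venom set so that the
    three conservation categories cover every venom protein.
    """
    clustered = {
        prot for members in clusters.clusters.values() for sp, prot in members
        if sp == focal_species
    }
    new = dict(clusters.clusters)
    for pid in sorted(set(venom_ids) - clustered):
        cid = f"{prefix}_{pid}"
        if cid in new:
            raise ValidationError(f"singleton cluster id collision: {cid!r}")
        new[cid] = [(focal_species, pid)]
    return OrthologyClusterSet(clusters=new, provenance=clusters.provenance)


def categorize_venom(
    clusters: OrthologyClusterSet,
    venom_ids: Iterable[str],
    groups: SpeciesGroups,
) -> dict[str, ConservationCategory]:
    """Assign each venom protein its conservation category.

    Every venom protein must already belong to a cluster (run
    :func:`augment_singletons` first if needed).
    """
    venom = set(venom_ids)
    cluster_of: dict[str, str] = {}
    species_in: dict[str, set[str]] = {}
    for cid, members in clusters.clusters.items():
        species_in[cid] = {sp for sp, _ in members}
        for sp, prot in members:
            if sp == groups.focal and prot in venom:
                cluster_of[prot] = cid

    missing = venom - set(cluster_of)
    if missing:
        raise ValidationError(
            f"venom proteins not in any cluster (run augment_singletons): "
            f"{sorted(missing)[:5]}"
        )

    out: dict[str, ConservationCategory] = {}
    for pid in venom:
        sps = species_in[cluster_of[pid]]
        if sps & groups.distant_group:
            out[pid] = ConservationCategory.DISTANT_CONSERVED
        elif sps & groups.sister_group:
            out[pid] = ConservationCategory.SISTER_CONSERVED
        else:
            out[pid] = ConservationCategory.FOCAL_SPECIFIC
    return out


def category_summary(
    categories: Mapping[str, ConservationCategory],
) -> pd.DataFrame:
    """Counts and percentages per conservation category.

    Returns a frame indexed by category (all three rows always present)
    with ``count`` and ``pct`` columns; counts sum to the venom size.
    """
    if not categories:
        raise ValidationError("empty category map")
    total = len(categories)
    rows = []
    for cat in ConservationCategory:
        n = sum(1 for c in categories.values() if c is cat)
        rows.append({"category": cat.value, "count": n, "pct": 100.0 * n / total})
    return pd.DataFrame(rows).set_index("category")


def venom_molar_breakdown(
    categories: Mapping[str, ConservationCategory],
    empai_records: Sequence[EmpaiRecord],
) -> dict[str, float]:
    """Percentage of venom molecules per conservation category.

    Sums emPAI molar fractions within each category. Besides the three
    exclusive categories the result carries ``steinernema_specific``, the
    pooled sister + focal share (proteins not conserved with the distant
    group), since that pooled figure is how genus-specific venom abundance
    is usually quoted.
    """
    recs = [r for r in empai_records if r.molar_fraction is not None]
    if not recs:
        raise ValidationError("empai records lack molar fractions")
    uncat = sorted({r.protein_id for r in recs} - set(categories))
    if uncat:
        raise ValidationError(
            f"proteins with emPAI but no conservation category: {uncat[:5]}"
        )
    out = {cat.value: 0.0 for cat in ConservationCategory}
    for r in recs:
        out[categories[r.protein_id].value] += 100.0 * r.molar_fraction
    out["steinernema_specific"] = (
        out[ConservationCategory.SISTER_CONSERVED.value]
        + out[ConservationCategory.FOCAL_SPECIFIC.value]
    )
    return out


def rank_clusters(
    clusters: OrthologyClusterSet,
    categories: Mapping[str, ConservationCategory],
    empai_records: Sequence[EmpaiRecord],
    groups: SpeciesGroups,
) -> pd.DataFrame:
    """Venom-conservation table: one row per cluster containing venom protein.

    Columns: per-species member counts, the cluster's category (from its
    venom members), ``fraction_of_venom`` (summed molar fraction of its venom
    members), and ``rank`` (1 = largest fraction; ties broken by cluster id).
    """
    frac = {r.protein_id: (r.molar_fraction or 0.0) for r in empai_records}
    species_order = sorted(groups.all_species)
    rows = []
    for cid, members in clusters.clusters.items():
        venom_members = [
            prot for sp, prot in members
            if sp == groups.focal and prot in categories
        ]
        if not venom_members:
            continue
        counts = {sp: 0 for sp in species_order}
        for sp, _ in members:
            counts[sp] = counts.get(sp, 0) + 1
        row = {"cluster_id": cid, **{f"n_{sp}": counts[sp] for sp in species_order}}
        row["n_venom"] = len(venom_members)
        row["category"] = categories[venom_members[0]].value
        row["fraction_of_venom"] = sum(frac.get(p, 0.0) for p in venom_members)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        ["fraction_of_venom", "cluster_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df
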