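"""Seeded synthetic-data generation with planted ground truth.

Every pipeline stage consumes standard text formats (FASTA, TSV, an
OrthoMCL-style groups file). This module fabricates all of them from a
single :class:`SyntheticDesign`, planting the quantities the analyses are
supposed to recover — conservation category counts, molar abundances,
differential-expression sets with a designed Venn overlap, per-batch
expression offsets, and operon-like proximity groups — and returns the
planted truth alongside, so tests can assert exact recovery.

The default design mirrors the headline shape of an activated-infective-
juvenile venom study: 472 venom proteins among 28,313 genes, 14 comparison
species, a 43% vertebrate-parasite-conserved venom fraction, an ~85%
genus-specific share of venom molecules, DE Venn overlaps of 135/210 and
65/88, and 79 of 178 queried genes in proximity groups. ``small()`` gives
a scaled-down variant for fast tests.

All generators are deterministic given ``design.seed``; each stage derives
an independent stream from the seed and a stage tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from venomkit import empai as _empai
from venomkit.conservation import ConservationCategory, OrthologyClusterSet, SpeciesGroups
from venomkit.errors import ValidationError
from venomkit.proteome_io import ProteinRecord, Proteome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: roughly uniform background with elevated K/R so tryptic peptides exist
_AA_WEIGHTS = np.array(
    [1.0, 0.6, 1.2, 1.4, 0.9, 1.5, 0.5, 1.2, 1.4, 2.0,
     0.5, 1.0, 1.0, 0.9, 1.3, 1.6, 1.2, 1.3, 0.3, 0.7]
)
_AA_P = _AA_WEIGHTS / _AA_WEIGHTS.sum()

_STAGE_TAGS = {
    "proteomes": 1, "clusters": 2, "abundance": 3, "peptides": 4,
    "expression": 5, "de": 6, "positions": 7, "domains": 8, "activation": 9,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), _STAGE_TAGS[stage]])


@dataclass(frozen=True)
class VennDesign:
    """Designed overlap of two DE gene sets (shared + exclusive counts)."""

    shared: int
    a_only: int
    b_only: int

    @property
    def union(self) -> int:
        return self.shared + self.a_only + self.b_only


@dataclass
class SyntheticDesign:
    seed: int = 0

    # species layout
    focal: str = "sc"
    sister_group: tuple[str, ...] = ("sf", "sg", "sm", "ssc")
    distant_group: tuple[str, ...] = ("ss", "tc", "bm", "hc", "as", "od", "ac", "dv")
    other: tuple[str, ...] = ("hb",)

    # focal proteome
    n_genes: int = 28313
    max_isoforms: int = 3
    seq_len_min: int = 80
    seq_len_max: int = 600
    n_genes_other: int = 300  # per non-focal species

    # venom catalog and conservation
    venom_size: int = 472
    n_venom_clusters: int = 321
    p_distant: float = 0.43
    p_sister: float = 0.22
    p_focal: float = 0.35

    # abundance model (log-normal on molar abundance)
    abundance_sigma: float = 1.0
    #: share of venom molecules carried by distant-conserved proteins
    distant_molar_share: float = 0.15

    # peptide observation model. "empai_inverse": detection probability
    # log10(1 + scale * A / median(A)), clipped to 1 — the model under which
    # emPAI is proportional to molar abundance, so planted shares are
    # recoverable. "logistic": logistic in standardized log-abundance.
    detection_model: str = "empai_inverse"
    detection_scale: float = 0.8
    detection_slope: float = 1.25
    detection_intercept: float = 0.0

    # expression design
    conditions: tuple[str, ...] = (
        "non_activated", "invitro_12h", "invivo_9h", "invivo_12h", "invivo_15h"
    )
    n_replicates: int = 3
    #: conditions processed on a different day, i.e. the second batch
    batch_b_conditions: tuple[str, ...] = ("invivo_9h", "invivo_12h")
    batch_offset_sd: float = 0.6
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    nb_dispersion: float = 0.1
    noiseless: bool = False
    n_de_up: int = 861
    n_de_down: int = 1406
    de_log2fc_scale: float = 1.2

    # DE-table Venn design (upregulated, downregulated venom genes)
    venn_up: VennDesign = field(default_factory=lambda: VennDesign(135, 38, 37))
    venn_down: VennDesign = field(default_factory=lambda: VennDesign(65, 12, 11))

    # proximity design
    n_proximity_query: int = 178
    proximity_group_sizes: tuple[int, ...] = (2,) * 20 + (3,) * 7 + (4,) * 2 + (5,) * 2
    proximity_window: int = 10
    n_scaffolds: int = 20

    # domain-family design: (name, accession, n_genome, n_venom)
    domain_families: tuple[tuple[str, str, int, int], ...] = (
        ("TILa domain", "PF12714.2", 16, 9),
        ("Serine carboxypeptidase", "PF00450.17", 24, 9),
        ("Trypsin", "PF00089.21", 114, 41),
        ("Ubiquitin-2 like Rad60 SUMO-like", "PF11976.3", 17, 6),
        ("Trypsin inhibitor-like cysteine-rich domain", "PF01826.12", 79, 26),
        ("Von Willebrand factor type A domain", "PF00092.23", 33, 10),
        ("Ubiquitin family", "PF00240.18", 29, 7),
        ("Eukaryotic aspartyl protease", "PF00026.18", 39, 9),
        ("Kunitz/Bovine pancreatic trypsin inhibitor domain", "PF00014.18", 43, 8),
        ("Zinc carboxypeptidase", "PF00246.19", 33, 6),
        ("Shk domain-like", "PF01549.19", 85, 14),
    )

    # activation time course
    activation_times_h: tuple[float, ...] = (6, 12, 18, 24, 30, 42, 54)
    activation_replicates: int = 3
    worms_per_replicate: int = 100

    def __post_init__(self) -> None:
        if abs(self.p_distant + self.p_sister + self.p_focal - 1.0) > 1e-9:
            raise ValidationError("category proportions must sum to 1")
        if self.venom_size > self.n_genes:
            raise ValidationError("venom_size exceeds n_genes")
        if sum(self.proximity_group_sizes) > self.n_proximity_query:
            raise ValidationError("proximity groups larger than the query set")

    @property
    def species_groups(self) -> SpeciesGroups:
        return SpeciesGroups(
            focal=self.focal,
            sister_group=frozenset(self.sister_group),
            distant_group=frozenset(self.distant_group),
            other=frozenset(self.other),
        )

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SyntheticDesign":
        """Scaled-down design for fast tests (same structure, ~1/50 size)."""
        base = dict(
            seed=seed,
            n_genes=400,
            n_genes_other=40,
            venom_size=60,
            n_venom_clusters=40,
            n_de_up=40,
            n_de_down=50,
            venn_up=VennDesign(14, 4, 4),
            venn_down=VennDesign(8, 2, 2),
            n_proximity_query=30,
            proximity_group_sizes=(2, 2, 3, 3, 4),
            n_scaffolds=5,
            domain_families=(
                ("TILa domain", "PF12714.2", 16, 9),
                ("Trypsin", "PF00089.21", 30, 11),
            ),
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# sequences and proteomes

def _random_sequences(rng: np.random.Generator, n: int, lmin: int, lmax: int) -> list[str]:
    lengths = rng.integers(lmin, lmax + 1, size=n)
    letters = rng.choice(list(AMINO_ACIDS), size=int(lengths.sum()), p=_AA_P)
    seqs, pos = [], 0
    for L in lengths:
        seqs.append("".join(letters[pos : pos + L]))
        pos += L
    return seqs


def make_proteomes(design: SyntheticDesign) -> dict[str, Proteome]:
    """Generate the focal proteome (with isoforms) and comparison proteomes.

    Focal protein ids follow the ``g<N>.t<K>`` scheme so the default FASTA
    header parser recovers gene ids; isoform counts are 1..max_isoforms.
    """
    rng = _rng(design.seed, "proteomes")
    proteomes: dict[str, Proteome] = {}

    n_iso = rng.integers(1, design.max_isoforms + 1, size=design.n_genes)
    total = int(n_iso.sum())
    seqs = _random_sequences(rng, total, design.seq_len_min, design.seq_len_max)
    records, k = [], 0
    for g in range(design.n_genes):
        gene = f"g{g + 1}"
        for t in range(int(n_iso[g])):
            records.append(
                ProteinRecord(
                    protein_id=f"{gene}.t{t + 1}",
                    gene_id=gene,
                    species_id=design.focal,
                    sequence=seqs[k],
                )
            )
            k += 1
    proteomes[design.focal] = Proteome(species_id=design.focal, records=records)

    for sp in (*design.sister_group, *design.distant_group, *design.other):
        seqs = _random_sequences(
            rng, design.n_genes_other, design.seq_len_min, design.seq_len_max
        )
        proteomes[sp] = Proteome(
            species_id=sp,
            records=[
                ProteinRecord(
                    protein_id=f"{sp}_p{i + 1}",
                    gene_id=f"{sp}_g{i + 1}",
                    species_id=sp,
                    sequence=s,
                )
                for i, s in enumerate(seqs)
            ],
        )
    return proteomes


def pick_venom_ids(design: SyntheticDesign, focal_filtered: Proteome) -> list[str]:
    """Choose the venom catalog: a seeded sample of focal representatives."""
    rng = np.random.default_rng([design.seed % (2**31), 101])
    ids = focal_filtered.protein_ids()
    idx = rng.choice(len(ids), size=design.venom_size, replace=False)
    return [ids[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# orthology clusters with planted conservation categories

def planted_category_counts(design: SyntheticDesign) -> dict[str, int]:
    v = design.venom_size
    n_distant = int(round(design.p_distant * v))
    n_sister = int(round(design.p_sister * v))
    return {
        ConservationCategory.DISTANT_CONSERVED.value: n_distant,
        ConservationCategory.SISTER_CONSERVED.value: n_sister,
        ConservationCategory.FOCAL_SPECIFIC.value: v - n_distant - n_sister,
    }


def make_clusters(
    design: SyntheticDesign,
    venom_ids: Sequence[str],
    proteomes: Mapping[str, Proteome] | None = None,
) -> tuple[OrthologyClusterSet, dict[str, ConservationCategory]]:
    """Build a groups-file cluster set realizing the planted category counts.

    Venom proteins are split into ``n_venom_clusters`` clusters; each
    cluster is decorated with non-focal members consistent with its planted
    category (distant clusters gain a distant-species member, sister
    clusters a sister member, focal-specific clusters at most an ``other``
    member, which does not promote them). Background clusters of non-venom
    proteins pad the file. Returns the cluster set and the per-protein
    planted truth.
    """
    rng = _rng(design.seed, "clusters")
    counts = planted_category_counts(design)
    venom = list(venom_ids)
    if len(venom) != design.venom_size:
        raise ValidationError("venom_ids length must equal design.venom_size")
    rng.shuffle(venom)

    cats = (
        [ConservationCategory.DISTANT_CONSERVED] * counts["distant_conserved"]
        + [ConservationCategory.SISTER_CONSERVED] * counts["sister_conserved"]
        + [ConservationCategory.FOCAL_SPECIFIC] * counts["focal_specific"]
    )
    truth = dict(zip(venom, cats))

    # sequential per-species allocation: a partner protein is never reused,
    # so a planted category cannot be demoted by a duplicate-member clash
    counters: dict[str, int] = {}

    def other_proteins(sp: str, n: int) -> list[str]:
        ids = []
        for _ in range(n):
            i = counters[sp] = counters.get(sp, 0) + 1
            if proteomes is not None and sp in proteomes and i <= len(proteomes[sp]):
                ids.append(proteomes[sp].records[i - 1].protein_id)
            else:
                ids.append(f"{sp}_p{i}")
        return ids

    # split each category's proteins into clusters so totals hit n_venom_clusters
    per_cat: dict[ConservationCategory, list[str]] = {c: [] for c in ConservationCategory}
    for pid, cat in truth.items():
        per_cat[cat].append(pid)
    n_clusters_cat = {
        c: max(1, int(round(design.n_venom_clusters * len(per_cat[c]) / len(venom))))
        for c in ConservationCategory
        if per_cat[c]
    }

    clusters: dict[str, list[tuple[str, str]]] = {}
    cidx = 0
    sisters = list(design.sister_group)
    distants = list(design.distant_group)
    others = list(design.other)
    for cat, members in per_cat.items():
        if not members:
            continue
        k = min(n_clusters_cat[cat], len(members))
        splits = np.array_split(np.array(members, dtype=object), k)
        for chunk in splits:
            cidx += 1
            cid = f"cluster{cidx:04d}"
            mem = [(design.focal, str(p)) for p in chunk]
            if cat is ConservationCategory.DISTANT_CONSERVED:
                for sp in rng.choice(distants, size=rng.integers(1, 4), replace=False):
                    mem += [(str(sp), p) for p in other_proteins(str(sp), 1)]
                if rng.random() < 0.5:  # distant precedence over sister members
                    sp = str(rng.choice(sisters))
                    mem += [(sp, p) for p in other_proteins(sp, 1)]
            elif cat is ConservationCategory.SISTER_CONSERVED:
                for sp in rng.choice(sisters, size=rng.integers(1, 3), replace=False):
                    mem += [(str(sp), p) for p in other_proteins(str(sp), 1)]
            else:
                if others and rng.random() < 0.2:  # 'other' never promotes
                    sp = str(rng.choice(others))
                    mem += [(sp, p) for p in other_proteins(sp, 1)]
            clusters[cid] = mem

    # background clusters of non-venom focal proteins with random partners
    n_bg = max(5, design.n_venom_clusters // 4)
    for b in range(n_bg):
        cidx += 1
        sp = str(rng.choice(distants + sisters))
        clusters[f"cluster{cidx:04d}"] = [
            (sp, p) for p in other_proteins(sp, int(rng.integers(2, 5)))
        ]

    return OrthologyClusterSet(clusters=clusters, provenance="synthetic"), truth


# ---------------------------------------------------------------------------
# molar abundances and peptide observations

def make_abundances(
    design: SyntheticDesign,
    categories: Mapping[str, ConservationCategory],
) -> pd.Series:
    """Planted molar abundances, log-normal, rescaled so distant-conserved
    proteins carry ``distant_molar_share`` of the total."""
    rng = _rng(design.seed, "abundance")
    pids = sorted(categories)
    ab = pd.Series(
        np.exp(rng.normal(0.0, design.abundance_sigma, size=len(pids))), index=pids
    )
    distant = [p for p in pids if categories[p] is ConservationCategory.DISTANT_CONSERVED]
    rest = [p for p in pids if p not in set(distant)]
    if distant and rest:
        target = design.distant_molar_share / (1.0 - design.distant_molar_share)
        ab.loc[distant] *= target * ab.loc[rest].sum() / ab.loc[distant].sum()
    return ab / ab.sum()


def make_peptide_observations(
    design: SyntheticDesign,
    proteome: Proteome,
    abundances: Mapping[str, float],
    dcfg: _empai.DigestionConfig | None = None,
    ocfg: _empai.ObservabilityConfig | None = None,
) -> tuple[list[_empai.PeptideObservation], list[str]]:
    """Simulate peptide identification driven by planted abundance.

    Each observable peptide of a protein is detected independently with a
    probability set by ``design.detection_model`` (see
    :class:`SyntheticDesign`). Returns the observations and the ids of
    proteins excluded for having no observable peptides.
    """
    rng = _rng(design.seed, "peptides")
    dcfg = dcfg or _empai.DigestionConfig()
    ocfg = ocfg or _empai.ObservabilityConfig()
    abundances = pd.Series(abundances)
    recs = {r.protein_id: r for r in proteome.records}
    missing = sorted(set(abundances.index) - set(recs))
    if missing:
        raise ValidationError(f"abundances for unknown proteins: {missing[:5]}")

    pids = sorted(abundances.index)
    logs = np.log(abundances.loc[pids].to_numpy())
    mu, sd = logs.mean(), logs.std() or 1.0
    median_ab = float(np.exp(np.median(logs)))

    def detection_prob(a: float) -> float:
        if design.detection_model == "empai_inverse":
            return min(1.0, float(np.log10(1.0 + design.detection_scale * a / median_ab)))
        if design.detection_model == "logistic":
            z = (np.log(a) - mu) / sd
            return float(
                1.0 / (1.0 + np.exp(-(design.detection_intercept + design.detection_slope * z)))
            )
        raise ValidationError(f"unknown detection_model {design.detection_model!r}")

    observations: list[_empai.PeptideObservation] = []
    excluded: list[str] = []
    for pid in pids:
        peps = sorted(_empai.observable_peptides(recs[pid].sequence, dcfg, ocfg))
        if not peps:
            excluded.append(pid)
            continue
        hits = rng.random(len(peps)) < detection_prob(float(abundances[pid]))
        for pep, hit in zip(peps, hits):
            if hit:
                observations.append(
                    _empai.PeptideObservation(
                        protein_id=pid,
                        peptide_sequence=pep,
                        n_parent_ions=1 + int(rng.poisson(0.5)),
                    )
                )
    return observations, excluded


# ---------------------------------------------------------------------------
# expression matrices, DE tables, positions

def sample_table(design: SyntheticDesign) -> pd.DataFrame:
    rows = []
    for cond in design.conditions:
        for r in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_r{r}",
                    "condition": cond,
                    "replicate": r,
                    "batch": "B" if cond in design.batch_b_conditions else "A",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def make_expression(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts matrix (genes x samples), sample metadata, and planted truth.

    Per-gene baseline log2 means, additive condition effects for planted DE
    genes (up/down relative to ``non_activated``), and an additive per-gene
    log2 batch offset for the second batch. In noiseless mode the counts
    are exactly 2^signal - 1, so log2(x+1) returns the planted signal;
    otherwise negative-binomial noise is applied around 2^signal.
    """
    rng = _rng(design.seed, "expression")
    meta = sample_table(design)
    genes = [f"g{i + 1}" for i in range(design.n_genes)]
    n_g, n_s = len(genes), len(meta)

    base = rng.normal(design.base_log2_mean, design.base_log2_sd, size=n_g).clip(0.1)
    de_ids = rng.choice(n_g, size=design.n_de_up + design.n_de_down, replace=False)
    up_ids, down_ids = de_ids[: design.n_de_up], de_ids[design.n_de_up :]
    effect = np.zeros(n_g)
    effect[up_ids] = 1.0 + rng.exponential(design.de_log2fc_scale, size=len(up_ids))
    effect[down_ids] = -(1.0 + rng.exponential(design.de_log2fc_scale, size=len(down_ids)))
    batch_offset = rng.normal(0.0, design.batch_offset_sd, size=n_g)

    activated = np.array([c != "non_activated" for c in meta["condition"]])
    in_b = (meta["batch"] == "B").to_numpy()
    signal = (
        base[:, None]
        + effect[:, None] * activated[None, :]
        + batch_offset[:, None] * in_b[None, :]
    )
    mean_counts = np.maximum(np.power(2.0, signal) - 1.0, 0.0)
    if design.noiseless:
        counts = mean_counts
    else:
        r = 1.0 / design.nb_dispersion
        p = r / (r + np.maximum(mean_counts, 1e-9))
        counts = rng.negative_binomial(r, p).astype(float)
    m = pd.DataFrame(counts, index=genes, columns=meta.index)

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "base_log2": base,
            "effect_log2": effect,
            "batch_offset_log2": batch_offset,
            "de": np.where(effect > 0, "up", np.where(effect < 0, "down", "none")),
        }
    )
    return m, meta, truth


def make_de_tables(
    design: SyntheticDesign, venom_genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, list[str]]]]:
    """Two DE tables (fold change + FDR) realizing the planted Venn design.

    Table A plays the in-vitro-activation contrast, table B the in-vivo
    one. Gene sets are drawn from ``venom_genes``; the planted up/down
    shared and exclusive counts follow ``design.venn_up`` / ``venn_down``.
    Non-DE genes are included with sub-threshold fold changes so that
    threshold filtering recovers the planted sets exactly.
    """
    rng = _rng(design.seed, "de")
    need = design.venn_up.union + design.venn_down.union
    if need > len(venom_genes):
        raise ValidationError(
            f"Venn design needs {need} genes but only {len(venom_genes)} available"
        )
    pool = list(venom_genes)
    rng.shuffle(pool)

    def take(n: int) -> list[str]:
        out, pool[:n] = pool[:n], []
        return out

    vu, vd = design.venn_up, design.venn_down
    up_shared, up_a, up_b = take(vu.shared), take(vu.a_only), take(vu.b_only)
    dn_shared, dn_a, dn_b = take(vd.shared), take(vd.a_only), take(vd.b_only)

    truth = {
        "a": {"up": sorted(up_shared + up_a), "down": sorted(dn_shared + dn_a)},
        "b": {"up": sorted(up_shared + up_b), "down": sorted(dn_shared + dn_b)},
    }

    def build(up: list[str], down: list[str]) -> pd.DataFrame:
        rows = []
        for g in venom_genes:
            if g in up:
                lfc = 1.05 + rng.exponential(design.de_log2fc_scale)
                fdr = rng.uniform(1e-6, 0.049)
            elif g in down:
                lfc = -(1.05 + rng.exponential(design.de_log2fc_scale))
                fdr = rng.uniform(1e-6, 0.049)
            else:
                lfc = rng.uniform(-0.95, 0.95)
                fdr = rng.uniform(0.0, 1.0)
            rows.append({"gene_id": g, "log2fc": lfc, "fdr": fdr})
        return pd.DataFrame(rows)

    table_a = build(set(up_shared + up_a), set(dn_shared + dn_a))
    table_b = build(set(up_shared + up_b), set(dn_shared + dn_b))
    return table_a, table_b, truth


def make_positions(
    design: SyntheticDesign,
    all_genes: Sequence[str],
    query_genes: Sequence[str],
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Ordinal gene positions planting the designed proximity groups.

    The first ``sum(proximity_group_sizes)`` query genes are laid out as
    tight runs (adjacent-gene gaps 1-3, well under the window) on the first
    scaffold, separated by more than the window; remaining query genes are
    isolated. Background genes fill every unused ordinal slot so each
    scaffold's indices are contiguous. Returns the positions table and the
    planted groups.
    """
    rng = _rng(design.seed, "positions")
    query = list(query_genes)
    if len(query) != design.n_proximity_query:
        raise ValidationError(
            f"expected {design.n_proximity_query} query genes, got {len(query)}"
        )
    sizes = design.proximity_group_sizes
    w = design.proximity_window

    planted: list[list[str]] = []
    placements: dict[str, int] = {}  # query gene -> ordinal on scaffold 1
    cursor = int(rng.integers(0, 3))
    qi = 0
    for s in sizes:
        group = query[qi : qi + s]
        qi += s
        idx = cursor
        for g in group:
            placements[g] = idx
            idx += int(rng.integers(1, 4))
        planted.append(group)
        cursor = placements[group[-1]] + w + 1 + int(rng.integers(1, 6))
    for g in query[qi:]:  # isolated query genes
        placements[g] = cursor
        cursor += w + 1 + int(rng.integers(1, 6))

    scaffold1_len = cursor + 5
    background = [g for g in all_genes if g not in placements]
    n_needed_s1 = scaffold1_len - len(placements)
    if n_needed_s1 > len(background):
        raise ValidationError("design infeasible: not enough background genes")

    rows = []
    used = set(placements.values())
    filler = iter(background[:n_needed_s1])
    for g, i in placements.items():
        rows.append({"gene_id": g, "scaffold_id": "scf1", "ordinal_index": i})
    for i in range(scaffold1_len):
        if i not in used:
            rows.append(
                {"gene_id": next(filler), "scaffold_id": "scf1", "ordinal_index": i}
            )

    rest = background[n_needed_s1:]
    n_other = max(1, design.n_scaffolds - 1)
    for k, chunk in enumerate(np.array_split(np.array(rest, dtype=object), n_other)):
        for i, g in enumerate(chunk):
            rows.append(
                {"gene_id": str(g), "scaffold_id": f"scf{k + 2}", "ordinal_index": i}
            )
    return pd.DataFrame(rows), planted


# ---------------------------------------------------------------------------
# domain hits and activation counts

def make_domain_hits(
    design: SyntheticDesign,
    focal_filtered: Proteome,
    venom_ids: Sequence[str],
) -> tuple[list, pd.DataFrame]:
    """Domain hits realizing the designed per-family genome/venom counts.

    Each family gets hits (E-value well under 1e-6) on ``n_venom`` venom
    proteins and ``n_genome - n_venom`` non-venom genes; a matching batch
    of decoy hits above the threshold exercises the E-value filter.
    """
    from venomkit.domain_stats import DomainHit

    rng = _rng(design.seed, "domains")
    venom = list(venom_ids)
    non_venom = [p for p in focal_filtered.protein_ids() if p not in set(venom)]

    hits: list[DomainHit] = []
    truth_rows = []
    for name, acc, n_genome, n_venom in design.domain_families:
        if n_venom > len(venom) or (n_genome - n_venom) > len(non_venom):
            raise ValidationError(f"family {acc}: design larger than proteome")
        vsel = [venom[int(i)] for i in rng.choice(len(venom), n_venom, replace=False)]
        bsel = [
            non_venom[int(i)]
            for i in rng.choice(len(non_venom), n_genome - n_venom, replace=False)
        ]
        for pid in vsel + bsel:
            hits.append(DomainHit(pid, acc, name, float(10.0 ** -rng.uniform(7, 30))))
        # decoys above threshold, on arbitrary proteins
        for pid in (non_venom[int(i)] for i in rng.integers(0, len(non_venom), 5)):
            hits.append(DomainHit(pid, acc, name, float(10.0 ** -rng.uniform(0, 5.5))))
        truth_rows.append(
            {"domain_accession": acc, "n_genome": n_genome, "n_venom": n_venom}
        )
    return hits, pd.DataFrame(truth_rows)


def make_activation_counts(design: SyntheticDesign) -> pd.DataFrame:
    """Activation time course: worms counted as non/partially/fully activated.

    The activated fraction rises logistically with time; the full-activation
    share within activated worms rises too. Counts are multinomial per
    replicate.
    """
    rng = _rng(design.seed, "activation")
    rows = []
    for t in design.activation_times_h:
        p_act = 1.0 / (1.0 + np.exp(-(t - 12.0) / 6.0))
        p_full_given_act = 1.0 / (1.0 + np.exp(-(t - 18.0) / 8.0))
        p_full = p_act * p_full_given_act
        p_partial = p_act - p_full
        for r in range(1, design.activation_replicates + 1):
            n_non, n_partial, n_full = rng.multinomial(
                design.worms_per_replicate, [1.0 - p_act, p_partial, p_full]
            )
            rows.append(
                {
                    "time_h": float(t),
                    "replicate": r,
                    "n_non": int(n_non),
                    "n_partial": int(n_partial),
                    "n_full": int(n_full),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle writer

def write_all(design: SyntheticDesign, outdir: str | Path) -> dict[str, str]:
    """Generate every synthetic input and write it under ``outdir``.

    Emits per-species FASTA, the groups file, venom id list, peptide
    observations, expression matrix + metadata, DE tables, positions,
    domain hits, activation counts, and a ``truth.json`` with the planted
    quantities. Returns a name -> path map.
    """
    from venomkit import proteome_io
    from venomkit.conservation import write_groups
    from venomkit.domain_stats import DomainHit  # noqa: F401  (type for hits)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    proteomes = make_proteomes(design)
    for sp, prot in proteomes.items():
        p = out / f"{sp}.fa"
        proteome_io.write_fasta(prot, p)
        paths[f"fasta_{sp}"] = str(p)

    focal_filtered = proteome_io.longest_isoform_filter(proteomes[design.focal])
    venom_ids = pick_venom_ids(design, focal_filtered)
    (out / "venom_ids.txt").write_text("\n".join(venom_ids) + "\n")
    paths["venom_ids"] = str(out / "venom_ids.txt")

    clusters, cat_truth = make_clusters(design, venom_ids, proteomes)
    write_groups(clusters, out / "groups.txt")
    paths["groups"] = str(out / "groups.txt")

    abundances = make_abundances(design, cat_truth)
    observations, excluded = make_peptide_observations(
        design, focal_filtered, abundances
    )
    pd.DataFrame(
        {
            "protein_id": [o.protein_id for o in observations],
            "peptide": [o.peptide_sequence for o in observations],
            "n_parent_ions": [o.n_parent_ions for o in observations],
        }
    ).to_csv(out / "peptides.tsv", sep="\t", index=False)
    paths["peptides"] = str(out / "peptides.tsv")

    m, meta, expr_truth = make_expression(design)
    m.to_csv(out / "expression.tsv", sep="\t")
    meta.to_csv(out / "samples.tsv", sep="\t")
    expr_truth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
    paths.update(
        expression=str(out / "expression.tsv"),
        samples=str(out / "samples.tsv"),
    )

    venom_genes = sorted({focal_filtered.gene_map()[p] for p in venom_ids})
    table_a, table_b, venn_truth = make_de_tables(design, venom_genes)
    table_a.assign(contrast="invitro_12h_vs_non").to_csv(
        out / "de_invitro.tsv", sep="\t", index=False
    )
    table_b.assign(contrast="invivo_15h_vs_non").to_csv(
        out / "de_invivo.tsv", sep="\t", index=False
    )
    paths.update(de_invitro=str(out / "de_invitro.tsv"), de_invivo=str(out / "de_invivo.tsv"))

    de_union = sorted(
        set(venn_truth["a"]["up"]) | set(venn_truth["b"]["up"])
        | set(venn_truth["a"]["down"]) | set(venn_truth["b"]["down"])
    )
    query = de_union[: design.n_proximity_query]
    if len(query) < design.n_proximity_query:
        extra = [g for g in venom_genes if g not in set(query)]
        query += extra[: design.n_proximity_query - len(query)]
    all_genes = [f"g{i + 1}" for i in range(design.n_genes)]
    positions, planted_groups = make_positions(design, all_genes, query)
    positions.to_csv(out / "positions.tsv", sep="\t", index=False)
    paths["positions"] = str(out / "positions.tsv")

    hits, dom_truth = make_domain_hits(design, focal_filtered, venom_ids)
    pd.DataFrame(
        {
            "protein_id": [h.protein_id for h in hits],
            "domain_accession": [h.domain_accession for h in hits],
            "domain_name": [h.domain_name for h in hits],
            "e_value": [h.e_value for h in hits],
        }
    ).to_csv(out / "domains.tsv", sep="\t", index=False)
    paths["domains"] = str(out / "domains.tsv")

    activation = make_activation_counts(design)
    activation.to_csv(out / "activation.tsv", sep="\t", index=False)
    paths["activation"] = str(out / "activation.tsv")

    truth = {
        "categories": {p: c.value for p, c in cat_truth.items()},
        "category_counts": planted_category_counts(design),
        "abundances": {p: float(a) for p, a in abundances.items()},
        "excluded_unobservable": excluded,
        "venn": venn_truth,
        "proximity_groups": planted_groups,
        "proximity_query": query,
        "domain_truth": dom_truth.to_dict("records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    paths["truth"] = str(out / "truth.json")
    return paths
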