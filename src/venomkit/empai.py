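"""emPAI abundance scoring from in-silico digestion and observed peptides.

The exponentially modified protein abundance index,

    emPAI = 10^(N_observed / N_observable) - 1,

is a spectral-count proxy for molar protein abundance: N_observed is the
number of distinct peptides identified for a protein, N_observable the
number of peptides its sequence could in principle yield inside the
instrument's scan range. emPAI divided by the summed emPAI of the whole
catalog estimates a protein's molar fraction of the mixture.

Digestion models a trypsin/Lys-C mix: cleavage C-terminal to K or R, with
the classical no-cleavage-before-proline exception applied to R only, since
Lys-C cleaves K-P bonds. Peptide masses are monoisotopic, with fixed
carbamidomethylation of cysteine (iodoacetamide alkylation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _pmass

from venomkit.errors import ValidationError
from venomkit.proteome_io import ProteinRecord, Proteome

WATER_MONO = 18.0105646863
CARBAMIDOMETHYL = 57.02146

#: monoisotopic residue masses; cysteine carries the fixed alkylation
RESIDUE_MASS: dict[str, float] = {
    aa: m for aa, m in _pmass.std_aa_mass.items() if len(aa) == 1 and aa.isupper()
}
RESIDUE_MASS["C"] += CARBAMIDOMETHYL


@dataclass(frozen=True)
class DigestionConfig:
    enzyme: str = "trypsin_lysC"
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    #: suppress cleavage at R-P bonds (K-P still cleaved by Lys-C)
    block_proline_after_r: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValidationError("max_missed_cleavages must be >= 0")
        if self.min_peptide_length < 1:
            raise ValidationError("min_peptide_length must be >= 1")


@dataclass(frozen=True)
class ObservabilityConfig:
    """m/z scan range and precursor charge states of the instrument."""

    mz_min: float = 300.0
    mz_max: float = 1800.0
    charge_min: int = 2
    charge_max: int = 6
    proton_mass: float = 1.00728

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValidationError("mz_min must be < mz_max")
        if not 1 <= self.charge_min <= self.charge_max:
            raise ValidationError("need 1 <= charge_min <= charge_max")


@dataclass(frozen=True)
class PeptideObservation:
    protein_id: str
    peptide_sequence: str
    n_parent_ions: int = 1

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValidationError("empty peptide sequence")
        if self.n_parent_ions < 1:
            raise ValidationError("n_parent_ions must be positive")


@dataclass(frozen=True)
class EmpaiRecord:
    protein_id: str
    n_observed: int
    n_observable: int
    empai: float
    molar_fraction: float | None = None


def cleavage_sites(sequence: str, cfg: DigestionConfig) -> list[int]:
    """Positions i such that the bond between sequence[i-1] and sequence[i]
    is cleaved. Only K and R are sites; non-standard residues never are."""
    sites: list[int] = []
    for i in range(len(sequence) - 1):
        aa = sequence[i]
        if aa == "K":
            sites.append(i + 1)
        elif aa == "R":
            if cfg.block_proline_after_r and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest(sequence: str, cfg: DigestionConfig) -> set[tuple[str, int]]:
    """In-silico digest: set of (peptide, missed_cleavage_count) pairs.

    Peptides are contiguous substrings bounded by cleavage sites or termini,
    carrying at most ``max_missed_cleavages`` internal sites and at least
    ``min_peptide_length`` residues.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    bounds = [0] + cleavage_sites(sequence, cfg) + [len(sequence)]
    out: set[tuple[str, int]] = set()
    n = len(bounds)
    for i in range(n - 1):
        for j in range(i + 1, min(i + 2 + cfg.max_missed_cleavages, n)):
            pep = sequence[bounds[i] : bounds[j]]
            if len(pep) >= cfg.min_peptide_length:
                out.add((pep, j - i - 1))
    return out


def peptide_mass(peptide: str) -> float:
    """Neutral monoisotopic mass in Da (residues + one water)."""
    total = WATER_MONO
    for aa in peptide:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValidationError(
                f"no monoisotopic mass for residue {aa!r}"
            ) from None
    return total


def observable_mass_window(cfg: ObservabilityConfig) -> tuple[float, float]:
    """Neutral-mass window [min, max] in Da reachable by some allowed charge.

    A precursor of neutral mass M at charge z appears at m/z = (M + z*mp)/z,
    so the union over charges of the in-range masses is the interval
    [mz_min*z_min - z_min*mp, mz_max*z_max - z_max*mp].
    """
    lo = cfg.mz_min * cfg.charge_min - cfg.charge_min * cfg.proton_mass
    hi = cfg.mz_max * cfg.charge_max - cfg.charge_max * cfg.proton_mass
    return lo, hi


def observable_peptides(
    sequence: str, dcfg: DigestionConfig, ocfg: ObservabilityConfig
) -> set[str]:
    """Distinct digest peptides whose neutral mass falls in the scan window."""
    lo, hi = observable_mass_window(ocfg)
    peps = {p for p, _ in digest(sequence, dcfg)}
    return {p for p in peps if lo <= peptide_mass(p) <= hi}


def count_observable(
    record: ProteinRecord, dcfg: DigestionConfig, ocfg: ObservabilityConfig
) -> int:
    """N_observable: distinct in-window digest peptides of one protein."""
    return len(observable_peptides(record.sequence, dcfg, ocfg))


def empai_score(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(N_obs/N_obsbl) - 1; zero when nothing was observed."""
    if n_observed == 0:
        return 0.0
    if n_observable <= 0:
        raise ValidationError(
            "protein has observed peptides but no observable peptides"
        )
    return 10.0 ** (n_observed / n_observable) - 1.0


def molar_fractions(records: Sequence[EmpaiRecord]) -> list[EmpaiRecord]:
    """Fill molar_fraction = emPAI_i / sum_j emPAI_j over the catalog."""
    total = sum(r.empai for r in records)
    if total <= 0:
        raise ValidationError("all emPAI scores are zero; fractions undefined")
    return [replace(r, molar_fraction=r.empai / total) for r in records]


def empai_table(
    proteome: Proteome,
    observations: Iterable[PeptideObservation],
    dcfg: DigestionConfig | None = None,
    ocfg: ObservabilityConfig | None = None,
    count_mode: str = "distinct",
) -> list[EmpaiRecord]:
    """Score every protein with at least one observed peptide.

    ``count_mode`` sets how N_observed is tallied: "distinct" counts distinct
    peptide sequences per protein (the convention of the emPAI literature);
    "ions" sums parent-ion counts instead. Molar fractions are filled over
    the returned catalog.
    """
    dcfg = dcfg or DigestionConfig()
    ocfg = ocfg or ObservabilityConfig()
    if count_mode not in ("distinct", "ions"):
        raise ValidationError(f"unknown count_mode {count_mode!r}")

    by_protein: dict[str, dict[str, int]] = {}
    for obs in observations:
        peps = by_protein.setdefault(obs.protein_id, {})
        peps[obs.peptide_sequence] = peps.get(obs.peptide_sequence, 0) + obs.n_parent_ions

    known = {r.protein_id: r for r in proteome.records}
    missing = sorted(set(by_protein) - set(known))
    if missing:
        raise ValidationError(
            f"observed proteins absent from proteome: {', '.join(missing[:5])}"
        )

    out: list[EmpaiRecord] = []
    for pid in by_protein:
        peps = by_protein[pid]
        n_obs = len(peps) if count_mode == "distinct" else sum(peps.values())
        n_obsbl = count_observable(known[pid], dcfg, ocfg)
        out.append(
            EmpaiRecord(
                protein_id=pid,
                n_observed=n_obs,
                n_observable=n_obsbl,
                empai=empai_score(n_obs, n_obsbl),
            )
        )
    return molar_fractions(out)


# ---------------------------------------------------------------------------
# tabular I/O

def read_peptide_tsv(path: str | Path) -> list[PeptideObservation]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "peptide", "n_parent_ions"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"peptide table must have columns {sorted(required)}"
        )
    return [
        PeptideObservation(r.protein_id, r.peptide, int(r.n_parent_ions))
        for r in df.itertuples(index=False)
    ]


def write_empai_tsv(records: Sequence[EmpaiRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "n_obs": [r.n_observed for r in records],
            "n_obsbl": [r.n_observable for r in records],
            "empai": [r.empai for r in records],
            "molar_fraction": [r.molar_fraction for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_empai_tsv(path: str | Path) -> list[EmpaiRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        EmpaiRecord(
            protein_id=r.protein_id,
            n_observed=int(r.n_obs),
            n_observable=int(r.n_obsbl),
            empai=float(r.empai),
            molar_fraction=(None if pd.isna(r.molar_fraction) else float(r.molar_fraction)),
        )
        for r in df.itertuples(index=False)
    ]
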