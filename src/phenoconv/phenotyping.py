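"""Diplotype-to-phenotype translation and phenoconversion.

The metabolizer phenotype is an ordinal category PM < IM < NM < UM derived
from the activity score of a star-allele diplotype.  Co-medication shifts
the effective phenotype ("phenoconversion"): a moderate inhibitor moves a
patient one category down, a strong inhibitor two categories down (both
clamped at PM), and a CYP2C19 inducer moves a patient one category up
(clamped at UM) — except that PMs stay PM under induction, because inducing
the synthesis of loss-of-function protein does not change clearance.  Weak
inhibitors trigger no shift.  CYP2D6 has no known inducers.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from phenoconv.knowledge_base import (
    GENES,
    AlleleTable,
    DrugKB,
    PhenotypeCutpoints,
    STAR_ALLELE_RE,
)

logger = logging.getLogger(__name__)


class Phenotype(enum.IntEnum):
    """Metabolizer category, totally ordered PM < IM < NM < UM."""

    PM = 0
    IM = 1
    NM = 2
    UM = 3

    def __str__(self) -> str:  # "PM" rather than "Phenotype.PM" in tables
        return self.name

    @classmethod
    def from_string(cls, s: str) -> "Phenotype":
        return cls[s.strip().upper()]

    def shifted(self, steps: int) -> "Phenotype":
        """Ordinal shift clamped to [PM, UM]."""
        return Phenotype(min(max(int(self) + steps, Phenotype.PM), Phenotype.UM))


class InhibitorStrength(enum.IntEnum):
    """Inhibitor strength ladder; the strongest co-medication wins."""

    NONE = 0
    WEAK = 1
    MODERATE = 2
    STRONG = 3


_ROLE_TO_STRENGTH = {
    "weak_inhibitor": InhibitorStrength.WEAK,
    "moderate_inhibitor": InhibitorStrength.MODERATE,
    "strong_inhibitor": InhibitorStrength.STRONG,
}


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star alleles for one gene (*1/*4 == *4/*1)."""

    gene: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        for a in (self.allele1, self.allele2):
            if not STAR_ALLELE_RE.match(a):
                raise ValueError(f"{self.gene}: invalid star allele {a!r}")
        # normalize order so the pair is genuinely unordered
        a1, a2 = sorted((self.allele1, self.allele2))
        object.__setattr__(self, "allele1", a1)
        object.__setattr__(self, "allele2", a2)

    def __str__(self) -> str:
        return f"{self.gene} {self.allele1}/{self.allele2}"


@dataclass(frozen=True)
class ModulatorExposure:
    """Summary of a patient's modulating co-medication for one gene."""

    gene: str
    strongest_inhibitor: InhibitorStrength = InhibitorStrength.NONE
    inducer_present: bool = False

    def __post_init__(self) -> None:
        if self.gene == "CYP2D6" and self.inducer_present:
            raise ValueError("no known inducers exist for CYP2D6")

    @property
    def conflicted(self) -> bool:
        """Moderate/strong inhibition and induction at once: no net rule exists."""
        return (
            self.strongest_inhibitor >= InhibitorStrength.MODERATE and self.inducer_present
        )


@dataclass(frozen=True)
class PhenotypePair:
    """Genotype-predicted and phenoconverted phenotype for one patient-gene."""

    predicted: Phenotype
    converted: Phenotype
    phenoconverted: bool
    conflict: bool = False


def translate_diplotype(
    d: Diplotype, table: AlleleTable, cutpoints: PhenotypeCutpoints
) -> Phenotype:
    """Translate a diplotype to its genotype-predicted phenotype.

    The activity score is the sum of the two alleles' activity values,
    classified through the gene's cut-points.  Symmetric in allele order by
    construction; unknown alleles raise ``KeyError`` naming the allele.
    """
    if d.gene != table.gene:
        raise ValueError(f"diplotype gene {d.gene} does not match table gene {table.gene}")
    score = table.activity(d.allele1) + table.activity(d.allele2)
    return cutpoints.classify(score)


def classify_modulators(
    meds: Iterable[str], kb: DrugKB, gene: str
) -> ModulatorExposure:
    """Reduce a medication list to the modulator exposure for one gene.

    The strongest inhibitor present wins (strong > moderate > weak > none);
    strengths do not stack.  Drugs the KB does not know are logged and
    ignored (they have no known CYP role).
    """
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}")
    strongest = InhibitorStrength.NONE
    inducer = False
    for med in meds:
        entry = kb.get(med)
        if entry is None:
            logger.info("%s: no known CYP role, ignored for modulator classification", med)
            continue
        role = entry.modulator_roles.get(gene)
        if role is None:
            continue
        if role == "inducer":
            inducer = True
        else:
            strongest = max(strongest, _ROLE_TO_STRENGTH[role])
    return ModulatorExposure(gene=gene, strongest_inhibitor=strongest, inducer_present=inducer)


def phenoconvert(p: Phenotype, exposure: ModulatorExposure) -> Phenotype:
    """Apply the phenoconversion shift rule to one phenotype.

    moderate inhibitor: one step down; strong inhibitor: two steps down
    (clamped at PM); inducer (CYP2C19 only): one step up clamped at UM,
    except PM stays PM.  Weak or no modulation: unchanged.  A simultaneous
    moderate/strong inhibitor and inducer is a conflict with no defined net
    rule: no shift is applied and a warning is emitted.
    """
    if exposure.conflicted:
        warnings.warn(
            f"{exposure.gene}: concurrent inhibitor and inducer - no net "
            "phenoconversion rule defined, phenotype left unshifted",
            stacklevel=2,
        )
        return p
    if exposure.strongest_inhibitor == InhibitorStrength.STRONG:
        return p.shifted(-2)
    if exposure.strongest_inhibitor == InhibitorStrength.MODERATE:
        return p.shifted(-1)
    if exposure.inducer_present:
        if p == Phenotype.PM:
            return Phenotype.PM
        return p.shifted(+1)
    return p


#: The phenoconversion table as published data: rows are genotype-predicted
#: phenotypes, columns the modulator classes.  Kept as a literal alongside
#: the rule in :func:`phenoconvert`; a test asserts cell-for-cell equality
#: so the table and the rule cannot drift apart.
CONVERSION_TABLE: dict[Phenotype, dict[str, Phenotype]] = {
    Phenotype.PM: {"moderate_inhibitor": Phenotype.PM, "strong_inhibitor": Phenotype.PM, "inducer": Phenotype.PM},
    Phenotype.IM: {"moderate_inhibitor": Phenotype.PM, "strong_inhibitor": Phenotype.PM, "inducer": Phenotype.NM},
    Phenotype.NM: {"moderate_inhibitor": Phenotype.IM, "strong_inhibitor": Phenotype.PM, "inducer": Phenotype.UM},
    Phenotype.UM: {"moderate_inhibitor": Phenotype.NM, "strong_inhibitor": Phenotype.IM, "inducer": Phenotype.UM},
}


def conversion_table_from_rule(gene: str = "CYP2C19") -> dict[Phenotype, dict[str, Phenotype]]:
    """Regenerate the phenoconversion table by evaluating the shift rule."""
    exposures = {
        "moderate_inhibitor": ModulatorExposure(gene, InhibitorStrength.MODERATE),
        "strong_inhibitor": ModulatorExposure(gene, InhibitorStrength.STRONG),
        "inducer": ModulatorExposure(gene, inducer_present=True),
    }
    return {
        p: {col: phenoconvert(p, exp) for col, exp in exposures.items()}
        for p in Phenotype
    }


def phenotype_cohort(
    genotypes: pd.DataFrame,
    medications: pd.DataFrame,
    kb: DrugKB,
    tables: Mapping[str, tuple[AlleleTable, PhenotypeCutpoints]],
    count_mode: str = "any_shift",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Phenotype and phenoconvert a whole cohort.

    Parameters
    ----------
    genotypes : DataFrame with columns patient_id, gene, allele1, allele2.
    medications : DataFrame with columns patient_id, drug (dose columns are
        ignored here).  Patients present in the medication table but missing
        a genotype for a gene are excluded from that gene with a log entry.
    count_mode : how the cohort phenoconversion proportion counts a patient:
        ``"any_shift"`` (default) counts predicted != converted;
        ``"modulator_user"`` counts any user of a moderate/strong inhibitor
        or an inducer, whether or not the category actually moved.

    Returns
    -------
    (per-patient table, rates): the table has one row per patient per gene
    with columns patient_id, gene, predicted, converted, phenoconverted,
    conflict_flag; rates maps gene -> phenoconversion proportion.
    """
    if count_mode not in ("any_shift", "modulator_user"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    meds_by_patient: dict = (
        medications.groupby("patient_id")["drug"].apply(list).to_dict()
        if len(medications)
        else {}
    )
    rows = []
    for (pid, gene), grp in genotypes.groupby(["patient_id", "gene"], sort=True):
        if gene not in tables:
            raise ValueError(f"no allele table for gene {gene!r}")
        rec = grp.iloc[0]
        table, cutpoints = tables[gene]
        d = Diplotype(gene=gene, allele1=rec["allele1"], allele2=rec["allele2"])
        predicted = translate_diplotype(d, table, cutpoints)
        exposure = classify_modulators(meds_by_patient.get(pid, []), kb, gene)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            converted = phenoconvert(predicted, exposure)
        if count_mode == "any_shift":
            flag = predicted != converted
        else:
            flag = (
                exposure.strongest_inhibitor >= InhibitorStrength.MODERATE
                or exposure.inducer_present
            )
        rows.append(
            {
                "patient_id": pid,
                "gene": gene,
                "predicted": str(predicted),
                "converted": str(converted),
                "phenoconverted": bool(flag),
                "conflict_flag": exposure.conflicted,
            }
        )
    # patients with medication but no genotype at all: excluded, logged
    genotyped = set(genotypes["patient_id"])
    for pid in sorted(set(meds_by_patient) - genotyped):
        logger.info("patient %s has no genotype; excluded from phenotyping", pid)
    result = pd.DataFrame(
        rows, columns=["patient_id", "gene", "predicted", "converted", "phenoconverted", "conflict_flag"]
    )
    rates = {
        gene: float(sub["phenoconverted"].mean()) if len(sub) else float("nan")
        for gene, sub in result.groupby("gene")
    }
    return result, rates
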