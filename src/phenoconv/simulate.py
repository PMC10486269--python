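"""Synthetic psychiatric-cohort generator.

Produces linked patient-level tables — genotypes, medications, UKU
questionnaire responses, measured drug levels, and demographics — with the
statistical structure the analysis pipeline assumes:

* diplotypes drawn under Hardy-Weinberg equilibrium from configurable
  star-allele frequencies;
* medication lists with configurable substrate-use and modulator-use
  probabilities per strength class (defaults calibrated to the observed
  outpatient-cohort margins: e.g. moderate/strong CYP2C19 inhibitor or
  inducer use in 12 of 117 patients) and a configurable polypharmacy
  (>= 5 drugs) prevalence;
* side-effect presence drawn from a per-item logistic model with
  coefficients for an IM/PM phenoconverted phenotype, polypharmacy and a
  non-psychotic diagnosis; severity conditional on presence;
* plasma concentrations proportional to dose over phenotype-dependent
  clearance, with multiplicative lognormal noise.

The generator emulates published cohort margins only; it makes no claim to
reproduce any real population's joint distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from phenoconv.knowledge_base import DrugKB, default_allele_tables, default_drug_kb
from phenoconv.phenotyping import (
    Diplotype,
    Phenotype,
    classify_modulators,
    phenoconvert,
    translate_diplotype,
)

#: synthetic European-ancestry-like allele frequencies (a convention for
#: testing, not a population claim); panels span all four phenotypes.
DEFAULT_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "CYP2C19": {"*1": 0.63, "*2": 0.15, "*17": 0.22},
    "CYP2D6": {"*1": 0.40, "*2": 0.27, "*4": 0.18, "*5": 0.03, "*10": 0.02, "*41": 0.08, "*1xN": 0.02},
}

#: modulator-use probabilities per strength class, calibrated to the
#: observed margins of a 117-patient outpatient cohort.
DEFAULT_MODULATOR_PROBS: dict[str, dict[str, float]] = {
    "CYP2C19": {"weak": 20 / 117, "moderate": 6 / 117, "strong": 3 / 117, "inducer": 3 / 117},
    "CYP2D6": {"weak": 15 / 117, "moderate": 0.0, "strong": 11 / 117, "inducer": 0.0},
}

DEFAULT_SUBSTRATE_PROBS: dict[str, float] = {"CYP2C19": 17 / 117, "CYP2D6": 52 / 117}

DEFAULT_CLEARANCE: dict[str, float] = {"NM": 1.0, "UM": 1.5, "IM": 0.6, "PM": 0.45}

#: typical daily doses (mg) used when a drug is assigned to a patient
TYPICAL_DOSE: dict[str, float] = {
    "aripiprazole": 10, "risperidone": 2, "haloperidol": 5, "venlafaxine": 150,
    "nortriptyline": 75, "amitriptyline": 75, "clomipramine": 100, "imipramine": 100,
    "zuclopenthixol": 20, "pimozide": 2, "paroxetine": 20, "citalopram": 20,
    "escitalopram": 10, "sertraline": 100, "diazepam": 10, "clozapine": 300,
}

#: CD-ratio scale (ug/L per mg at clearance 1) per measured substrate
CD_SCALE: dict[str, float] = {
    "aripiprazole": 8.0, "risperidone": 15.0, "haloperidol": 1.5, "venlafaxine": 1.0,
}


@dataclass(frozen=True)
class SideEffectModel:
    """Per-item logistic presence model plus conditional severity law."""

    baseline_logodds: Mapping[str, float] = field(default_factory=dict)
    default_baseline: float = -1.0
    beta_impm: float = 0.9       # converted IM/PM phenotype of `gene`
    beta_polypharmacy: float = 1.5
    beta_nonpsychotic: float = 0.95
    gene: str = "CYP2D6"
    severity_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) given present

    def logodds(self, item: str) -> float:
        return float(self.baseline_logodds.get(item, self.default_baseline))


#: items absent from every patient in practice (exercises the excluded-item
#: path downstream): effectively zero baseline odds
NEVER_PRESENT_LOGODDS = {
    "epileptic_seizures": -12.0,
    "amenorrhea": -12.0,
    "galactorrhea": -12.0,
}


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort."""

    n_patients: int = 117
    seed: int = 0
    allele_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_ALLELE_FREQS.items()}
    )
    substrate_use_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTRATE_PROBS)
    )
    modulator_use_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_MODULATOR_PROBS.items()}
    )
    polypharmacy_prev: float = 68 / 117
    psychotic_prev: float = 72 / 117
    bmi_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"<30": 30 / 117, "30-40": 55 / 117, ">40": 31 / 117}
    )
    uku_nonresponse_prob: float = 13 / 117
    side_effect_model: SideEffectModel = field(
        default_factory=lambda: SideEffectModel(baseline_logodds=dict(NEVER_PRESENT_LOGODDS))
    )
    clearance_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLEARANCE)
    )
    concentration_noise: float = 0.3  # lognormal sigma on the multiplicative error

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for gene, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene} allele frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{gene} has a negative allele frequency")
        for gene, probs in self.modulator_use_probs.items():
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"{gene} modulator probabilities outside [0,1]")
            if sum(probs.values()) > 1 + 1e-9:
                raise ValueError(f"{gene} modulator class probabilities sum above 1")
        for name, p in [
            ("polypharmacy_prev", self.polypharmacy_prev),
            ("psychotic_prev", self.psychotic_prev),
            ("uku_nonresponse_prob", self.uku_nonresponse_prob),
            *((f"substrate_use_prob[{g}]", p) for g, p in self.substrate_use_prob.items()),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} = {p} outside [0,1]")
        if any(m <= 0 for m in self.clearance_multipliers.values()):
            raise ValueError("clearance multipliers must be positive")
        if self.concentration_noise < 0:
            raise ValueError("concentration_noise must be non-negative")
        if abs(sum(self.side_effect_model.severity_probs) - 1.0) > 1e-9:
            raise ValueError("severity probabilities must sum to 1")


def hardy_weinberg_draw(freqs: Mapping[str, float], rng: np.random.Generator) -> tuple[str, str]:
    """Draw an unordered allele pair i.i.d. from the allele frequencies."""
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles], dtype=float)
    p = p / p.sum()
    pair = rng.choice(alleles, size=2, p=p)
    return tuple(sorted(pair))  # type: ignore[return-value]


_MOD_CLASS_ROLE = {
    "weak": "weak_inhibitor",
    "moderate": "moderate_inhibitor",
    "strong": "strong_inhibitor",
    "inducer": "inducer",
}

#: inert co-medications with no CYP2C19/CYP2D6 role
_FILLER_DRUGS = tuple(f"comed_{i:02d}" for i in range(1, 21))


def _shifts_other(kb: DrugKB, drug: str, gene: str) -> bool:
    """True if the drug carries a shift-inducing role for another gene."""
    return any(
        g != gene and role != "weak_inhibitor"
        for g, role in kb.get(drug).modulator_roles.items()
    )


def generate_cohort(
    spec: CohortSpec,
    kb: DrugKB | None = None,
    tables=None,
    items=None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Generate one cohort; identical (spec, seed) gives identical tables.

    Returns ``(tables, truth)`` where ``tables`` holds the five linked
    DataFrames (``genotype``, ``medication``, ``uku``, ``drug_level``,
    ``patients``) and ``truth`` records the latent per-patient state
    (phenotypes, exposure classes) plus the generating parameters, for
    parameter-recovery tests.
    """
    from phenoconv.uku import default_item_set

    spec.validate()
    kb = kb or default_drug_kb()
    tables_ = tables or default_allele_tables()
    items = items or default_item_set()
    rng = np.random.default_rng(spec.seed)
    sem = spec.side_effect_model

    genotype_rows, med_rows, uku_rows, level_rows, patient_rows = [], [], [], [], []
    truth_patients = []

    genes = sorted(spec.allele_freqs)
    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        diplos: dict[str, tuple[str, str]] = {}
        predicted: dict[str, Phenotype] = {}
        for gene in genes:
            a1, a2 = hardy_weinberg_draw(spec.allele_freqs[gene], rng)
            diplos[gene] = (a1, a2)
            table, cp = tables_[gene]
            predicted[gene] = translate_diplotype(Diplotype(gene, a1, a2), table, cp)
            genotype_rows.append({"patient_id": pid, "gene": gene, "allele1": a1, "allele2": a2})

        meds: list[str] = []
        mod_class: dict[str, str] = {}
        for gene in genes:
            probs = spec.modulator_use_probs.get(gene, {})
            classes = ["weak", "moderate", "strong", "inducer"]
            p = np.array([probs.get(c, 0.0) for c in classes])
            draw = rng.choice(classes + ["none"], p=np.append(p, 1 - p.sum()))
            mod_class[gene] = draw
            if draw != "none":
                # restrict to drugs carrying no shift-inducing role beyond the
                # drawn one, so the per-class use probabilities stay marginally
                # calibrated (fluoxetine-style multi-gene modulators would leak
                # phenoconversion into the other gene); weak roles are harmless
                pool = [
                    d for d in kb.modulators(gene, _MOD_CLASS_ROLE[draw])
                    if not _shifts_other(kb, d, gene) and not kb.get(d).substrate_of
                ]
                if not pool:
                    raise ValueError(f"default KB has no single-role {draw} modulator for {gene}")
                meds.append(pool[int(rng.integers(len(pool)))])
            if rng.random() < spec.substrate_use_prob.get(gene, 0.0):
                # substrates with no shift-inducing modulator role, same reason
                pool = [
                    d for d in kb.substrates(gene)
                    if d not in meds
                    and not any(r != "weak_inhibitor" for r in kb.get(d).modulator_roles.values())
                ]
                meds.append(pool[int(rng.integers(len(pool)))])

        polypharmacy = rng.random() < spec.polypharmacy_prev
        target_n = int(rng.integers(5, 11)) if polypharmacy else int(rng.integers(0, 5))
        target_n = max(target_n, len(meds))
        fillers = rng.choice(_FILLER_DRUGS, size=target_n - len(meds), replace=False)
        meds = list(dict.fromkeys(meds)) + list(fillers)
        for drug in meds:
            med_rows.append(
                {"patient_id": pid, "drug": drug, "dose_mg_per_day": TYPICAL_DOSE.get(drug, 50.0)}
            )

        converted: dict[str, Phenotype] = {}
        for gene in genes:
            exp = classify_modulators(meds, kb, gene)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                converted[gene] = phenoconvert(predicted[gene], exp)

        psychotic = rng.random() < spec.psychotic_prev
        bmi_labels = sorted(spec.bmi_class_probs)
        bmi_p = np.array([spec.bmi_class_probs[k] for k in bmi_labels], dtype=float)
        bmi_class = str(rng.choice(bmi_labels, p=bmi_p / bmi_p.sum()))
        patient_rows.append(
            {
                "patient_id": pid,
                "diagnosis_group": "psychotic" if psychotic else "non-psychotic",
                "bmi_class": bmi_class,
            }
        )

        responded = rng.random() >= spec.uku_nonresponse_prob
        if responded:
            impm = converted.get(sem.gene, Phenotype.NM) in (Phenotype.IM, Phenotype.PM)
            for item in items.all_items:
                logit = (
                    sem.logodds(item)
                    + sem.beta_impm * impm
                    + sem.beta_polypharmacy * polypharmacy
                    + sem.beta_nonpsychotic * (not psychotic)
                )
                present = rng.random() < 1.0 / (1.0 + np.exp(-logit))
                sev = 1 + int(rng.choice(3, p=sem.severity_probs)) if present else 0
                uku_rows.append({"patient_id": pid, "item": item, "severity": sev})

        for gene in genes:
            for drug in meds:
                entry = kb.get(drug)
                if entry is None or gene not in entry.substrate_of or not entry.actionable:
                    continue
                dose = TYPICAL_DOSE.get(drug, 50.0)
                scale = CD_SCALE.get(drug, 5.0)
                clearance = spec.clearance_multipliers[str(converted[gene])]
                noise = float(np.exp(rng.normal(0.0, spec.concentration_noise)))
                conc = dose * scale / clearance * noise
                level_rows.append(
                    {
                        "patient_id": pid,
                        "drug": drug,
                        "concentration_ug_per_L": conc,
                        "dose_mg": dose,
                    }
                )

        truth_patients.append(
            {
                "patient_id": pid,
                **{f"predicted_{g}": str(predicted[g]) for g in genes},
                **{f"converted_{g}": str(converted[g]) for g in genes},
                **{f"modulator_class_{g}": mod_class[g] for g in genes},
                "polypharmacy": polypharmacy,
                "psychotic": psychotic,
                "uku_responded": responded,
            }
        )

    out = {
        "genotype": pd.DataFrame(genotype_rows, columns=["patient_id", "gene", "allele1", "allele2"]),
        "medication": pd.DataFrame(med_rows, columns=["patient_id", "drug", "dose_mg_per_day"]),
        "uku": pd.DataFrame(uku_rows, columns=["patient_id", "item", "severity"]),
        "drug_level": pd.DataFrame(
            level_rows, columns=["patient_id", "drug", "concentration_ug_per_L", "dose_mg"]
        ),
        "patients": pd.DataFrame(patient_rows, columns=["patient_id", "diagnosis_group", "bmi_class"]),
    }
    truth = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "beta_impm": sem.beta_impm,
        "beta_polypharmacy": sem.beta_polypharmacy,
        "beta_nonpsychotic": sem.beta_nonpsychotic,
        "clearance_multipliers": dict(spec.clearance_multipliers),
        "patients": pd.DataFrame(truth_patients),
    }
    return out, truth
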