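"""End-to-end analysis pipeline with a reproducible run manifest.

Stage order: phenotype translation and phenoconversion, UKU scoring,
association statistics (rank tests, crude and adjusted odds ratios,
per-item prevalence comparisons), and concentration-dose ratio analysis.
Patients lacking UKU data remain in the phenotyping output but are
excluded from the score and association stages; the manifest records
patients in / excluded / analyzed at every stage and reconciles exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

import phenoconv
from phenoconv.exposure import compare_cd_by_phenotype, default_pairing
from phenoconv.knowledge_base import DrugKB, default_allele_tables, default_drug_kb
from phenoconv.phenotyping import Phenotype, phenotype_cohort
from phenoconv.stats import (
    crude_or,
    dichotomize_outcome,
    logistic_mle,
    prevalence_test,
    rank_tests,
    StatsError,
)
from phenoconv.uku import ItemSet, default_item_set, prevalence_table, score_cohort

logger = logging.getLogger(__name__)

REQUIRED_TABLES = ("genotype", "medication", "uku", "drug_level", "patients")

_SCHEMAS = {
    "genotype": ["patient_id", "gene", "allele1", "allele2"],
    "medication": ["patient_id", "drug", "dose_mg_per_day"],
    "uku": ["patient_id", "item", "severity"],
    "drug_level": ["patient_id", "drug", "concentration_ug_per_L", "dose_mg"],
    "patients": ["patient_id", "diagnosis_group", "bmi_class"],
}


class PipelineError(RuntimeError):
    """A stage failed validation; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = phenoconv.__version__
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record_stage(self, name: str, n_in: int, excluded: int) -> None:
        self.stages[name] = {"in": n_in, "excluded": excluded, "analyzed": n_in - excluded}

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "input_digests": self.input_digests,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _validate_inputs(tables: Mapping[str, pd.DataFrame]) -> None:
    for name in REQUIRED_TABLES:
        if name not in tables:
            raise PipelineError("load", f"missing input table {name!r}")
        missing = set(_SCHEMAS[name]) - set(tables[name].columns)
        if missing:
            raise PipelineError("load", f"table {name!r} lacks columns {sorted(missing)}")
    if tables["genotype"].empty:
        raise PipelineError("load", "genotype table is empty; nothing to analyze")


def _phenotype_group(label: str) -> str | None:
    p = Phenotype.from_string(label)
    return "NM+UM" if p in (Phenotype.NM, Phenotype.UM) else "IM+PM"


def substrate_users(medication: pd.DataFrame, kb: DrugKB, gene: str) -> set:
    """Patients using an actionable substrate of the gene."""
    subs = set(kb.substrates(gene, actionable_only=True))
    used = medication[medication["drug"].str.lower().isin(subs)]
    return set(used["patient_id"])


def run_pipeline(
    tables: Mapping[str, pd.DataFrame],
    kb: DrugKB | None = None,
    allele_tables=None,
    items: ItemSet | None = None,
    config: dict | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    count_mode: str = "any_shift",
) -> tuple[dict, RunManifest]:
    """Run the full analysis over the five linked input tables.

    Returns a results bundle (phenotypes, uku_scores, phenoconversion
    rates, associations, prevalence, cd_ratio DataFrames) and the
    :class:`RunManifest`.  With ``outdir`` set, every table is written as
    CSV plus the manifest as JSON.
    """
    kb = kb or default_drug_kb()
    allele_tables = allele_tables or default_allele_tables()
    items = items or default_item_set()
    _validate_inputs(tables)
    manifest = RunManifest(config=dict(config or {}), seed=seed)
    manifest.input_digests = {name: _digest(tables[name]) for name in REQUIRED_TABLES}

    # --- stage 1: phenotyping -------------------------------------------
    genotype, medication = tables["genotype"], tables["medication"]
    all_patients = sorted(set(genotype["patient_id"]) | set(medication["patient_id"]))
    pheno_df, rates = phenotype_cohort(genotype, medication, kb, allele_tables, count_mode=count_mode)
    genotyped = sorted(set(genotype["patient_id"]))
    manifest.record_stage("phenotyping", len(all_patients), len(all_patients) - len(genotyped))

    # --- stage 2: UKU scoring -------------------------------------------
    uku = tables["uku"]
    responders = sorted(set(uku["patient_id"]) & set(genotyped))
    uku_scores, responses = score_cohort(uku[uku["patient_id"].isin(responders)], items)
    manifest.record_stage("uku_scoring", len(genotyped), len(genotyped) - len(responders))

    # --- stage 3: associations ------------------------------------------
    patients = tables["patients"].set_index("patient_id")
    scored = uku_scores.set_index("patient_id")
    frame = scored.join(patients, how="inner")
    frame["n_drugs"] = medication.groupby("patient_id")["drug"].nunique().reindex(frame.index).fillna(0)
    frame["polypharmacy"] = frame["n_drugs"] >= 5
    frame["non_psychotic"] = frame["diagnosis_group"].eq("non-psychotic")
    frame["outcome"] = [dichotomize_outcome(c) for c in frame["category"]]

    assoc_rows = []

    def _crude(name: str, exposed: pd.Series, subset: pd.DataFrame | None = None) -> None:
        sub = subset if subset is not None else frame
        exposed = exposed.reindex(sub.index).astype(bool)
        a = int(((exposed) & (sub["outcome"] == 1)).sum())
        b = int(((exposed) & (sub["outcome"] == 0)).sum())
        c = int(((~exposed) & (sub["outcome"] == 1)).sum())
        d = int(((~exposed) & (sub["outcome"] == 0)).sum())
        res = crude_or([[a, b], [c, d]])
        assoc_rows.append(
            {
                "comparison": name, "kind": "crude_or", "n": len(sub),
                "estimate": res.odds_ratio, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "test_used": res.test_used,
                "flags": "haldane_anscombe" if res.correction_applied else "",
            }
        )

    _crude("polypharmacy", frame["polypharmacy"])
    _crude("non_psychotic_diagnosis", frame["non_psychotic"])

    for grouping, label in [("polypharmacy", "polypharmacy"), ("non_psychotic", "non_psychotic_diagnosis")]:
        groups = [g["total"].to_numpy() for _, g in frame.groupby(grouping)]
        if len(groups) == 2:
            res = rank_tests(groups)
            assoc_rows.append(
                {
                    "comparison": f"uku_total_by_{label}", "kind": "rank_test", "n": len(frame),
                    "estimate": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"),
                    "p_value": res.p_value, "test_used": res.test_used, "flags": "",
                }
            )

    # phenotype-group ORs among substrate users, predicted and converted
    pheno_wide = pheno_df.pivot(index="patient_id", columns="gene", values=["predicted", "converted"])
    prevalence_rows = []
    for gene in sorted(set(pheno_df["gene"])):
        users = substrate_users(medication, kb, gene) & set(frame.index)
        for which in ("predicted", "converted"):
            sub = frame.loc[sorted(users)].copy()
            if not len(sub):
                continue
            labels = pheno_wide[(which, gene)].reindex(sub.index)
            sub["group"] = [_phenotype_group(v) for v in labels]
            name = f"{'P-' if which == 'converted' else ''}{gene}_IM+PM_vs_NM+UM"
            _crude(name, sub["group"].eq("IM+PM"), subset=sub)
            # adjusted logistic on the substrate-user subset
            covs = pd.DataFrame(
                {
                    "im_pm": sub["group"].eq("IM+PM").astype(float),
                    "polypharmacy": sub["polypharmacy"].astype(float),
                    "non_psychotic": sub["non_psychotic"].astype(float),
                },
                index=sub.index,
            )
            try:
                fit = logistic_mle(sub["outcome"].to_numpy(), covs)
                row = fit.results().set_index("covariate").loc["im_pm"]
                assoc_rows.append(
                    {
                        "comparison": name, "kind": "adjusted_or", "n": len(sub),
                        "estimate": row["odds_ratio"], "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"], "p_value": row["p_value"],
                        "test_used": "wald_logistic",
                        "flags": "separation" if row["separation_flag"] else "",
                    }
                )
            except StatsError as exc:
                assoc_rows.append(
                    {
                        "comparison": name, "kind": "adjusted_or", "n": len(sub),
                        "estimate": float("nan"), "ci_low": float("nan"),
                        "ci_high": float("nan"), "p_value": float("nan"),
                        "test_used": "wald_logistic", "flags": f"not_fit:{exc}",
                    }
                )

            # per-item prevalence comparisons, CYP-related items only
            groups_map = {pid: g for pid, g in zip(sub.index, sub["group"])}
            for item in items.all_items:
                if item not in items.cyp_related:
                    continue
                pt = prevalence_table(responses, item, groups_map)
                if pt.excluded:
                    prevalence_rows.append(
                        {
                            "gene": gene, "phenotype_basis": which, "item": item,
                            "n_nm_um": int(sum(pt.counts[0])), "n_im_pm": int(sum(pt.counts[1])),
                            "prev_nm_um": float("nan"), "prev_im_pm": float("nan"),
                            "p_value": float("nan"), "test_used": "", "excluded": True,
                        }
                    )
                    continue
                arr = pt.as_array()
                try:
                    p, used = prevalence_test(arr)
                except StatsError:
                    p, used = float("nan"), ""
                n1, n2 = arr.sum(axis=1)
                prevalence_rows.append(
                    {
                        "gene": gene, "phenotype_basis": which, "item": item,
                        "n_nm_um": int(n1), "n_im_pm": int(n2),
                        "prev_nm_um": arr[0, 0] / n1 if n1 else float("nan"),
                        "prev_im_pm": arr[1, 0] / n2 if n2 else float("nan"),
                        "p_value": p, "test_used": used, "excluded": False,
                    }
                )
    manifest.record_stage("associations", len(frame), 0)

    # --- stage 4: CD-ratio analysis -------------------------------------
    drug_level = tables["drug_level"]
    cd_results = {}
    for which in ("predicted", "converted"):
        cd_frames = []
        for gene in sorted(set(pheno_df["gene"])):
            pheno_map = {
                pid: Phenotype.from_string(v)
                for pid, v in pheno_wide[(which, gene)].dropna().items()
            }
            subs = set(kb.substrates(gene, actionable_only=True))
            rec = drug_level[drug_level["drug"].str.lower().isin(subs)]
            rec = rec[rec["patient_id"].isin(pheno_map)]
            if not len(rec):
                continue
            out = compare_cd_by_phenotype(rec, pheno_map, pairing=default_pairing())
            out.insert(0, "gene", gene)
            cd_frames.append(out)
        cd_results[which] = (
            pd.concat(cd_frames, ignore_index=True) if cd_frames else pd.DataFrame()
        )
    n_measured = len(set(drug_level["patient_id"]))
    manifest.record_stage("cd_ratio", n_measured, 0)

    results = {
        "phenotypes": pheno_df,
        "phenoconversion_rates": rates,
        "uku_scores": uku_scores,
        "associations": pd.DataFrame(assoc_rows),
        "prevalence": pd.DataFrame(prevalence_rows),
        "cd_ratio_predicted": cd_results.get("predicted", pd.DataFrame()),
        "cd_ratio_converted": cd_results.get("converted", pd.DataFrame()),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "phenoconversion_rates.json").write_text(json.dumps(rates, indent=2))
        (outdir / "manifest.json").write_text(manifest.to_json())
    return results, manifest
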