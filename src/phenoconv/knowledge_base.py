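"""Drug and allele knowledge bases.

Two configuration artefacts parameterize everything downstream:

* a **drug knowledge base** assigning each drug its substrate and modulator
  roles per gene (weak / moderate / strong inhibitor, or inducer), with an
  ``actionable`` flag marking substrates for which a therapeutic
  recommendation exists for the drug-gene interaction;
* an **allele table** per gene assigning each star allele a functional
  activity value, plus cut-points mapping the diplotype activity score to
  the four metabolizer categories.

Both ship with editable plain-text defaults under ``phenoconv/data``.  The
default drug list is a reconstruction from public inhibitor/inducer strength
classifications (FDA / Flockhart-style) covering the psychiatric substrates
and modulators relevant to CYP2C19 and CYP2D6; it is the single source of
truth and fully user-replaceable.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

GENES = ("CYP2C19", "CYP2D6")

MODULATOR_ROLES = ("weak_inhibitor", "moderate_inhibitor", "strong_inhibitor", "inducer")
_ROLES = ("substrate",) + MODULATOR_ROLES

#: star allele: "*" + digits, optional duplication suffix "xN" or "x<digits>"
STAR_ALLELE_RE = re.compile(r"^\*\d+(x(N|\d+))?$")


class KBError(ValueError):
    """Raised for malformed or invalid knowledge-base input."""


@dataclass(frozen=True)
class DrugEntry:
    """Substrate/modulator roles of one drug.

    A drug may be substrate and modulator simultaneously (fluoxetine is a
    CYP2D6 substrate's worst enemy and a CYP2C19 moderate inhibitor at the
    same time); per gene at most one modulator role is allowed, and CYP2D6
    never carries an inducer role — no CYP2D6 inducers are known.
    """

    name: str
    substrate_of: frozenset[str] = frozenset()
    modulator_roles: Mapping[str, str] = field(default_factory=dict)
    actionable: bool = True

    def __post_init__(self) -> None:
        if self.modulator_roles.get("CYP2D6") == "inducer":
            raise KBError(f"{self.name}: CYP2D6 cannot carry an inducer role")
        for gene, role in self.modulator_roles.items():
            if gene not in GENES:
                raise KBError(f"{self.name}: unknown gene {gene!r}")
            if role not in MODULATOR_ROLES:
                raise KBError(f"{self.name}: unknown modulator role {role!r}")
        for gene in self.substrate_of:
            if gene not in GENES:
                raise KBError(f"{self.name}: unknown gene {gene!r}")


class DrugKB:
    """Collection of :class:`DrugEntry`, keyed by normalized (lowercase) name."""

    def __init__(self, entries: Iterable[DrugEntry] = ()):
        self._entries: dict[str, DrugEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: DrugEntry) -> None:
        self._entries[entry.name.lower()] = entry

    def get(self, name: str) -> DrugEntry | None:
        """Case-insensitive exact lookup; None for drugs with no known CYP role."""
        return self._entries.get(name.strip().lower())

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def substrates(self, gene: str, actionable_only: bool = True) -> list[str]:
        return sorted(
            e.name
            for e in self
            if gene in e.substrate_of and (e.actionable or not actionable_only)
        )

    def modulators(self, gene: str, role: str) -> list[str]:
        return sorted(e.name for e in self if e.modulator_roles.get(gene) == role)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DrugKB):
            return NotImplemented
        return {e.name: e for e in self} == {e.name: e for e in other}


def load_drug_kb(path: str | Path) -> DrugKB:
    """Load a drug knowledge base from delimiter-separated text.

    Expected columns: ``drug, gene, role, actionable`` where role is one of
    substrate | weak_inhibitor | moderate_inhibitor | strong_inhibitor |
    inducer and actionable is 0/1 (only meaningful for substrate rows).
    Multiple rows per drug accumulate into one :class:`DrugEntry`.

    Raises :class:`KBError` naming the offending line for malformed rows,
    unknown genes/roles, duplicate modulator roles, or a CYP2D6 inducer.
    """
    path = Path(path)
    raw: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [(i, row) for i, row in enumerate(reader, start=1) if row and any(row)]
    if not rows:
        logger.warning("drug KB %s is empty", path)
        return DrugKB()
    start = 0
    if [c.strip().lower() for c in rows[0][1][:2]] == ["drug", "gene"]:
        start = 1
    for lineno, row in rows[start:]:
        if len(row) < 3:
            raise KBError(f"{path}:{lineno}: expected at least 3 columns, got {len(row)}")
        drug = row[0].strip().lower()
        gene = row[1].strip()
        role = row[2].strip().lower()
        actionable = row[3].strip() if len(row) > 3 and row[3].strip() else "1"
        if not drug:
            raise KBError(f"{path}:{lineno}: empty drug name")
        if gene not in GENES:
            raise KBError(f"{path}:{lineno}: unknown gene {gene!r}")
        if role not in _ROLES:
            raise KBError(f"{path}:{lineno}: unknown role {role!r}")
        if actionable not in ("0", "1"):
            raise KBError(f"{path}:{lineno}: actionable must be 0 or 1, got {actionable!r}")
        rec = raw.setdefault(drug, {"substrate_of": set(), "modulator_roles": {}, "actionable": True})
        if role == "substrate":
            rec["substrate_of"].add(gene)
            rec["actionable"] = rec["actionable"] and actionable == "1"
        else:
            if gene == "CYP2D6" and role == "inducer":
                raise KBError(f"{path}:{lineno}: CYP2D6 cannot have an inducer "
                              "(no CYP2D6 inducers are known)")
            if gene in rec["modulator_roles"] and rec["modulator_roles"][gene] != role:
                raise KBError(
                    f"{path}:{lineno}: {drug} already has modulator role "
                    f"{rec['modulator_roles'][gene]!r} for {gene}"
                )
            rec["modulator_roles"][gene] = role
    return DrugKB(
        DrugEntry(
            name=name,
            substrate_of=frozenset(rec["substrate_of"]),
            modulator_roles=dict(rec["modulator_roles"]),
            actionable=rec["actionable"],
        )
        for name, rec in raw.items()
    )


def write_drug_kb(kb: DrugKB, path: str | Path) -> None:
    """Write a KB back to the tabular text format; round-trips with load."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug", "gene", "role", "actionable"])
        for entry in sorted(kb, key=lambda e: e.name):
            for gene in sorted(entry.substrate_of):
                writer.writerow([entry.name, gene, "substrate", int(entry.actionable)])
            for gene in sorted(entry.modulator_roles):
                writer.writerow([entry.name, gene, entry.modulator_roles[gene], 1])


@dataclass(frozen=True)
class AlleleTable:
    """Per-gene mapping star allele -> functional activity value (>= 0)."""

    gene: str
    activities: Mapping[str, float]

    def __post_init__(self) -> None:
        if "*1" not in self.activities:
            raise KBError(f"{self.gene}: reference allele '*1' missing from allele table")
        for allele, act in self.activities.items():
            if not STAR_ALLELE_RE.match(allele):
                raise KBError(f"{self.gene}: {allele!r} is not a valid star-allele name")
            if act < 0:
                raise KBError(f"{self.gene}: allele {allele} has negative activity {act}")

    def activity(self, allele: str) -> float:
        """Activity of one allele.

        Duplication alleles not listed explicitly fall back to the base
        allele's activity times the copy number ("xN" counts as 2 copies).
        """
        allele = allele.strip()
        if allele in self.activities:
            return float(self.activities[allele])
        m = re.match(r"^(\*\d+)x(N|\d+)$", allele)
        if m and m.group(1) in self.activities:
            copies = 2 if m.group(2) == "N" else int(m.group(2))
            return float(self.activities[m.group(1)]) * copies
        raise KeyError(f"unknown {self.gene} allele {allele!r}")

    def __contains__(self, allele: str) -> bool:
        try:
            self.activity(allele)
            return True
        except KeyError:
            return False


@dataclass(frozen=True)
class PhenotypeCutpoints:
    """Activity-score intervals mapping to PM / IM / NM / UM.

    The intervals are ``[0, pm_max]`` -> PM, ``(pm_max, im_max]`` -> IM,
    ``(im_max, nm_max]`` -> NM and ``(nm_max, inf)`` -> UM: disjoint,
    ordered, and jointly covering the non-negative half-line, with 0 always
    in the PM interval.
    """

    gene: str
    pm_max: float
    im_max: float
    nm_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.pm_max < self.im_max < self.nm_max):
            raise KBError(
                f"{self.gene}: cutpoints must satisfy 0 <= pm_max < im_max < nm_max, "
                f"got ({self.pm_max}, {self.im_max}, {self.nm_max})"
            )

    def classify(self, activity_score: float) -> "Phenotype":
        from phenoconv.phenotyping import Phenotype

        if activity_score < 0:
            raise ValueError(f"negative activity score {activity_score}")
        if activity_score <= self.pm_max:
            return Phenotype.PM
        if activity_score <= self.im_max:
            return Phenotype.IM
        if activity_score <= self.nm_max:
            return Phenotype.NM
        return Phenotype.UM


def load_allele_tables(path: str | Path) -> dict[str, tuple[AlleleTable, PhenotypeCutpoints]]:
    """Load per-gene allele activities and phenotype cut-points from YAML.

    The config must list both CYP2C19 and CYP2D6, each with an ``alleles``
    mapping (star allele -> activity) and a ``cutpoints`` mapping with keys
    ``pm_max``, ``im_max``, ``nm_max``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out: dict[str, tuple[AlleleTable, PhenotypeCutpoints]] = {}
    for gene in GENES:
        if gene not in cfg:
            raise KBError(f"allele config {path} omits gene {gene}")
        section = cfg[gene]
        table = AlleleTable(gene=gene, activities={str(k): float(v) for k, v in section["alleles"].items()})
        cp = section["cutpoints"]
        out[gene] = (
            table,
            PhenotypeCutpoints(gene=gene, pm_max=float(cp["pm_max"]),
                               im_max=float(cp["im_max"]), nm_max=float(cp["nm_max"])),
        )
    unknown = set(cfg) - set(GENES)
    if unknown:
        raise KBError(f"allele config {path} lists unsupported genes: {sorted(unknown)}")
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("phenoconv").joinpath("data", name)))


def default_drug_kb() -> DrugKB:
    """The packaged default drug knowledge base."""
    return load_drug_kb(_data_path("drug_kb.csv"))


def default_allele_tables() -> dict[str, tuple[AlleleTable, PhenotypeCutpoints]]:
    """The packaged default allele activities and cut-points."""
    return load_allele_tables(_data_path("alleles.yaml"))
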