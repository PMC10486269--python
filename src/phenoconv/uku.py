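"""Scoring of the adapted UKU side-effect rating scale.

Each side effect is rated 0-3; the total score is the plain sum over all
items, a higher total meaning more or more severe side effects.  Totals are
categorized low / moderate / high at tertile-based cut-points (defaults:
low <= 11, moderate 12-21, high >= 22).  Per-item "presence" (severity >= 1)
feeds the per-side-effect prevalence comparisons, which are restricted to
the CYP-related subset of items and to CYP-substrate users, with phenotype
groups combined as NM+UM versus IM+PM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CATEGORIES = ("low", "moderate", "high")

#: default category cut-points: low <= 11, moderate 12..21, high >= 22.
#: The published intervals leave the total 21 unassigned (moderate printed
#: as 12-20, high as >= 22); 21 is folded into "moderate" so the three
#: categories partition all non-negative totals.
DEFAULT_CUTPOINTS: tuple[int, int] = (11, 21)


@dataclass(frozen=True)
class ItemSet:
    """Ordered adapted-UKU item list plus its CYP-related subset."""

    all_items: tuple[str, ...]
    cyp_related: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.all_items)) != len(self.all_items):
            raise ValueError("duplicate item names")
        extra = self.cyp_related - set(self.all_items)
        if extra:
            raise ValueError(f"cyp_related items not in all_items: {sorted(extra)}")


def default_item_set() -> ItemSet:
    """The packaged 39-item adapted UKU list (33 CYP-related)."""
    path = Path(str(resources.files("phenoconv").joinpath("data", "uku_items.yaml")))
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    items = tuple(rec["name"] for rec in cfg["items"])
    cyp = frozenset(rec["name"] for rec in cfg["items"] if rec["cyp_related"])
    return ItemSet(all_items=items, cyp_related=cyp)


@dataclass(frozen=True)
class UKUResponse:
    """One patient's scored questionnaire."""

    patient_id: object
    item_scores: Mapping[str, int]
    total: int
    category: str
    presence: Mapping[str, bool] = field(default_factory=dict)
    n_missing: int = 0


def categorize_total(total: int, cutpoints: tuple[int, int] = DEFAULT_CUTPOINTS) -> str:
    """Map a total score to low / moderate / high."""
    if total < 0:
        raise ValueError(f"negative total {total}")
    low_max, moderate_max = cutpoints
    if total <= low_max:
        return "low"
    if total <= moderate_max:
        return "moderate"
    return "high"


def tertile_cutpoints(totals: Sequence[int]) -> tuple[int, int]:
    """Data-driven tertile boundaries for a cohort's totals.

    Returns integer cut-points (t1, t2) such that ``categorize_total``
    splits the cohort approximately into thirds.
    """
    arr = np.asarray(totals, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 totals to estimate tertiles")
    t1, t2 = np.quantile(arr, [1 / 3, 2 / 3])
    return int(np.floor(t1)), int(np.floor(t2))


def score_uku(
    patient_id: object,
    raw: Mapping[str, int],
    items: ItemSet,
    cutpoints: tuple[int, int] = DEFAULT_CUTPOINTS,
) -> UKUResponse:
    """Score one patient's raw per-item severities.

    Severities must be integers in 0-3; unknown item names are an error.
    Items absent from ``raw`` are imputed as 0 (side effect not reported)
    and counted in ``n_missing``.
    """
    scores: dict[str, int] = {}
    for item, sev in raw.items():
        if item not in items.all_items:
            raise ValueError(f"unknown UKU item {item!r}")
        sev = int(sev)
        if not 0 <= sev <= 3:
            raise ValueError(f"severity {sev} for item {item!r} outside 0-3")
        scores[item] = sev
    n_missing = 0
    for item in items.all_items:
        if item not in scores:
            scores[item] = 0
            n_missing += 1
    total = sum(scores.values())
    return UKUResponse(
        patient_id=patient_id,
        item_scores=scores,
        total=total,
        category=categorize_total(total, cutpoints),
        presence={item: scores[item] >= 1 for item in items.all_items},
        n_missing=n_missing,
    )


def score_cohort(
    uku: pd.DataFrame,
    items: ItemSet | None = None,
    cutpoints: tuple[int, int] = DEFAULT_CUTPOINTS,
) -> tuple[pd.DataFrame, list[UKUResponse]]:
    """Score a long-format cohort table (columns patient_id, item, severity).

    Returns a per-patient summary table (patient_id, total, category,
    n_missing) and the full list of responses.
    """
    items = items or default_item_set()
    responses = []
    for pid, grp in uku.groupby("patient_id", sort=True):
        raw = dict(zip(grp["item"], grp["severity"]))
        responses.append(score_uku(pid, raw, items, cutpoints))
    summary = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "total": r.total,
                "category": r.category,
                "n_missing": r.n_missing,
            }
            for r in responses
        ],
        columns=["patient_id", "total", "category", "n_missing"],
    )
    return summary, responses


@dataclass(frozen=True)
class PrevalenceTable:
    """2x2 present/absent counts for one item across two phenotype groups."""

    item: str
    counts: tuple[tuple[int, int], tuple[int, int]]  # rows: groups; cols: present, absent
    group_labels: tuple[str, str]
    excluded: bool = False  # item absent in every contributing patient

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def prevalence_table(
    responses: Iterable[UKUResponse],
    item: str,
    groups: Mapping[object, str],
    group_labels: tuple[str, str] = ("NM+UM", "IM+PM"),
) -> PrevalenceTable:
    """Build the present/absent x group 2x2 table for one item.

    ``groups`` maps patient_id to one of the two group labels; patients not
    in the mapping (non-substrate-users) do not contribute.  An item never
    present in any contributing patient is flagged ``excluded``; an empty
    group yields a zero margin and a logged warning.
    """
    counts = {lab: [0, 0] for lab in group_labels}
    for r in responses:
        lab = groups.get(r.patient_id)
        if lab is None:
            continue
        if lab not in counts:
            raise ValueError(f"group label {lab!r} not in {group_labels}")
        if item not in r.presence:
            raise ValueError(f"unknown UKU item {item!r}")
        counts[lab][0 if r.presence[item] else 1] += 1
    table = tuple(tuple(counts[lab]) for lab in group_labels)
    total_present = sum(row[0] for row in table)
    for lab in group_labels:
        if sum(counts[lab]) == 0:
            logger.warning("prevalence table for %s: group %s is empty", item, lab)
    return PrevalenceTable(
        item=item,
        counts=table,  # type: ignore[arg-type]
        group_labels=group_labels,
        excluded=total_present == 0,
    )
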