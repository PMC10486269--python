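"""Concentration-dose ratios and phenotype-group exposure comparisons.

The CD-ratio (plasma concentration in ug/L divided by daily dose in mg) is
a dose-normalized exposure proxy: slower metabolizers clear less drug per
unit time and show higher CD-ratios at the same dose.  Ratios are compared
between NM and IM+PM groups (UM handling configurable) per drug; drugs
with fewer than two users in any group are excluded from the comparison.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from phenoconv.phenotyping import Phenotype

logger = logging.getLogger(__name__)


def cd_ratio(concentration: float, dose: float) -> float:
    """Concentration-dose ratio in ug/L per mg; dose must be positive."""
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    return concentration / dose


def default_pairing(include_um_with_nm: bool = False) -> Callable[[Phenotype], str | None]:
    """Group assignment for CD analysis: NM vs IM+PM.

    UMs are excluded by default (their clearance is not comparable to NM);
    set ``include_um_with_nm`` to fold them into the NM group.
    """

    def pairing(p: Phenotype) -> str | None:
        if p == Phenotype.NM:
            return "NM"
        if p in (Phenotype.IM, Phenotype.PM):
            return "IM+PM"
        return "NM" if include_um_with_nm else None

    return pairing


def compare_cd_by_phenotype(
    records: pd.DataFrame,
    phenotypes: Mapping[object, Phenotype],
    pairing: Callable[[Phenotype], str | None] | None = None,
    min_users: int = 2,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-drug CD-ratio comparison between phenotype groups.

    Parameters
    ----------
    records : DataFrame with columns patient_id, drug,
        concentration_ug_per_L, dose_mg.
    phenotypes : patient_id -> phenotype (typically the phenoconverted
        phenotype of the gene metabolizing each drug).  Every record's
        patient must be present.
    pairing : phenotype -> group label or None (excluded patient).
    min_users : minimum users per group for a drug to be analyzed.
    test : "welch" (two-sample t, unequal variances) or "mann_whitney".

    Returns one row per drug with group n / mean / SD, the p-value, and an
    ``excluded`` flag with the reason for drugs failing the user rule.
    """
    if test not in ("welch", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    pairing = pairing or default_pairing()
    missing = set(records["patient_id"]) - set(phenotypes)
    if missing:
        raise ValueError(f"no phenotype for patients: {sorted(missing)[:5]}")
    work = records.copy()
    work["cd_ratio"] = [
        cd_ratio(c, d) for c, d in zip(work["concentration_ug_per_L"], work["dose_mg"])
    ]
    work["group"] = [pairing(phenotypes[pid]) for pid in work["patient_id"]]
    work = work[work["group"].notna()]
    rows = []
    for drug, grp in work.groupby("drug", sort=True):
        g1 = grp.loc[grp["group"] == "NM", "cd_ratio"].to_numpy()
        g2 = grp.loc[grp["group"] == "IM+PM", "cd_ratio"].to_numpy()
        row = {
            "drug": drug,
            "n_nm": len(g1),
            "mean_nm": float(np.mean(g1)) if len(g1) else float("nan"),
            "sd_nm": float(np.std(g1, ddof=1)) if len(g1) > 1 else float("nan"),
            "n_impm": len(g2),
            "mean_impm": float(np.mean(g2)) if len(g2) else float("nan"),
            "sd_impm": float(np.std(g2, ddof=1)) if len(g2) > 1 else float("nan"),
        }
        if len(g1) < min_users or len(g2) < min_users:
            reason = f"fewer than {min_users} users in a phenotype group"
            logger.info("drug %s excluded from CD comparison: %s", drug, reason)
            row.update(p_value=float("nan"), test_used=None, excluded=True, reason=reason)
        else:
            if test == "welch":
                if np.ptp(grp["cd_ratio"].to_numpy()) == 0:
                    p = 1.0  # all ratios identical: no evidence of a difference
                else:
                    p = float(sps.ttest_ind(g1, g2, equal_var=False).pvalue)
                used = "welch_t"
            else:
                res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
                p, used = float(res.pvalue), "mann_whitney"
            row.update(p_value=p, test_used=used, excluded=False, reason="")
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) and out["excluded"].all():
        logger.warning("all drugs excluded from CD-ratio comparison")
    return out
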