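"""Cohort inclusion/exclusion rules and follow-up selection.

The analysis cohorts are produced by a short chain of filters, each of
which returns the kept patients together with a :class:`FilterAudit` so the
flow of exclusions can be reconciled exactly (input = kept + excluded, one
reason per excluded patient):

* follow-up selection: the initial assessment is the earliest one; the
  follow-up is the assessment closest to 60 days post-onset among those at
  least two months (60 days) after onset, ties broken toward the earlier
  date.  Patients with no qualifying follow-up are excluded.
* complete-injury exclusion: CST injury of 1 (16/16 subsections) — recovery
  proportional to injury cannot be assessed, the patient is dropped.
* ceiling filters: initial FMA-UE > 59 (scale max 66 minus the 6.6-point
  MCID) or initial FMA-LE > 27 excluded, to avoid ceiling effects.  Both
  cuts are strict ``>`` as printed; note 34 - 6 = 28 while the LE rule
  keeps <= 27 — the published rule is applied verbatim.
* severity stratification: partition on the initial score with ``>= cut``
  defining the high (mild) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FilterAudit",
    "select_followup",
    "select_followup_records",
    "ceiling_filter",
    "exclude_complete_injury",
    "stratify_by_threshold",
    "CEILING",
]

#: ceiling-exclusion cuts per limb: keep initial <= cut
CEILING = {"UE": 59, "LE": 27}
_INITIAL_COL = {"UE": "initial_fma_ue", "LE": "initial_fma_le"}
_FOLLOW_COL = {"UE": "followup_fma_ue", "LE": "followup_fma_le"}

MIN_FOLLOWUP_DAYS = 60
TARGET_FOLLOWUP_DAYS = 60


@dataclass
class FilterAudit:
    """Bookkeeping for one filter step."""

    rule: str
    n_in: int
    n_kept: int
    reasons: dict[str, str] = field(default_factory=dict)  # patient_id -> reason

    @property
    def n_excluded(self) -> int:
        return self.n_in - self.n_kept

    def __post_init__(self) -> None:
        if len(self.reasons) != self.n_excluded:
            raise ValueError("each excluded patient needs exactly one reason")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "n_excluded": self.n_excluded,
            "reasons": dict(self.reasons),
        }


def select_followup(
    assessments: pd.DataFrame,
    target_days: int = TARGET_FOLLOWUP_DAYS,
    min_days: int = MIN_FOLLOWUP_DAYS,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Pick initial and follow-up assessments per patient.

    ``assessments`` needs columns patient_id, days_from_onset, fma_ue,
    fma_le.  Returns one row per kept patient with initial_/followup_
    columns, plus an audit of patients excluded for incomplete FMA data.
    """
    rows = []
    reasons = {}
    ids = assessments["patient_id"].unique()
    for pid, grp in assessments.groupby("patient_id", sort=False):
        grp = grp.sort_values("days_from_onset")
        initial = grp.iloc[0]
        candidates = grp.iloc[1:]
        candidates = candidates[candidates["days_from_onset"] >= min_days]
        if candidates.empty:
            reasons[pid] = "incomplete FMA data"
            continue
        offset = (candidates["days_from_onset"] - target_days).abs()
        # ties broken toward the earlier date: stable idxmin on sorted rows
        follow = candidates.loc[offset.idxmin()]
        rows.append(
            {
                "patient_id": pid,
                "initial_day": int(initial["days_from_onset"]),
                "initial_fma_ue": int(initial["fma_ue"]),
                "initial_fma_le": int(initial["fma_le"]),
                "followup_day": int(follow["days_from_onset"]),
                "followup_fma_ue": int(follow["fma_ue"]),
                "followup_fma_le": int(follow["fma_le"]),
            }
        )
    kept = pd.DataFrame(rows)
    audit = FilterAudit("followup_selection", n_in=len(ids), n_kept=len(rows), reasons=reasons)
    return kept, audit


def select_followup_records(
    days_scores: list[tuple[int, int, int]],
    target_days: int = TARGET_FOLLOWUP_DAYS,
    min_days: int = MIN_FOLLOWUP_DAYS,
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Single-patient variant on (days_from_onset, fma_ue, fma_le) tuples.

    Raises ``ValueError`` when no qualifying follow-up exists.
    """
    if len(days_scores) < 2:
        raise ValueError("incomplete FMA data: need at least two assessments")
    ordered = sorted(days_scores, key=lambda t: t[0])
    initial = ordered[0]
    candidates = [t for t in ordered[1:] if t[0] >= min_days]
    if not candidates:
        raise ValueError("incomplete FMA data: no follow-up >= 2 months after onset")
    follow = min(candidates, key=lambda t: (abs(t[0] - target_days), t[0]))
    return initial, follow


def ceiling_filter(
    cohort: pd.DataFrame, limb: str, ceiling: int | None = None
) -> tuple[pd.DataFrame, FilterAudit]:
    """Drop patients whose initial score exceeds the limb's ceiling cut.

    Keeps initial <= ceiling (strict ``>`` excludes), default cuts 59 (UE)
    and 27 (LE).
    """
    col = _INITIAL_COL[limb]
    cut = CEILING[limb] if ceiling is None else ceiling
    keep = cohort[col] <= cut
    reasons = {
        pid: f"initial FMA-{limb} > {cut} (ceiling)"
        for pid in cohort.loc[~keep, "patient_id"]
    }
    audit = FilterAudit(f"ceiling_{limb}", n_in=len(cohort), n_kept=int(keep.sum()), reasons=reasons)
    return cohort[keep].reset_index(drop=True), audit


def exclude_complete_injury(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterAudit]:
    """Drop patients with complete (100%) CST involvement, injury == 1."""
    keep = cohort["cst_injury"] < 1.0
    reasons = {pid: "complete CST involvement (injury = 1)" for pid in cohort.loc[~keep, "patient_id"]}
    audit = FilterAudit(
        "complete_injury", n_in=len(cohort), n_kept=int(keep.sum()), reasons=reasons
    )
    return cohort[keep].reset_index(drop=True), audit


def stratify_by_threshold(
    cohort: pd.DataFrame, limb: str, cut: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition on the initial score: (below cut, at or above cut).

    The high stratum is ``initial >= cut`` — e.g. the FMA-UE >= 35 cluster
    excluded from the severe-stratum reanalysis.
    """
    col = _INITIAL_COL[limb]
    high = cohort[col] >= cut
    return (
        cohort[~high].reset_index(drop=True),
        cohort[high].reset_index(drop=True),
    )
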