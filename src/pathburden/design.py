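"""Matched extreme case-control design.

Patients with an invasive disease-free survival (iDFS) event strictly within
the first five years after diagnosis are cases (poor prognosis); patients
followed for at least five years with no event through last follow-up are
controls (favorable prognosis); everyone else — censored before five years,
or with an event at/after five years — is ineligible and the reason is
recorded.  An event at exactly 5.0 years is treated as *not* a case (the
case window is the half-open interval [0, 5)); such a patient is also not a
control, since they did have an event.

Each case is matched 1:1 to a randomly selected, previously unused control
with the same molecular subtype (St Gallen 2013 surrogate classes from ER,
PR, HER2 and Ki-67).  When a case's HER2 status is unknown the subtype is
Unclassified and the matching key falls back to the (ER, PR) combination.
No caliper is applied to age or any other continuous variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CASE_WINDOW_YEARS = 5.0

SUBTYPES = ["LuminalA", "LuminalB", "TNBC", "HER2", "Unclassified"]


def classify_subtype(
    er: str,
    pr: str,
    her2: str,
    ki67: float | None,
    ki67_cutoff: float = 20.0,
) -> str:
    """St Gallen 2013 surrogate subtype from receptor status and Ki-67 (%).

    Rules (pos/neg/unknown status strings; unknown Ki-67 passed as None/NaN):

    * Luminal A: ER+ and PR+ and HER2- and Ki-67 < cutoff
    * Luminal B: ER+ and (HER2+ or Ki-67 >= cutoff or PR-)
    * HER2-enriched: ER- and PR- and HER2+
    * TNBC: ER- and PR- and HER2-
    * Unclassified: any field needed to decide is unknown, or a combination
      not covered above (e.g. ER-/PR+).

    Unknowns are handled with three-valued logic: a rule fires only when its
    condition is definitively true given the known fields, so e.g. ER+/PR-
    is Luminal B even if HER2 is unknown, while ER+ with unknown HER2 and
    low Ki-67 cannot be resolved and is Unclassified.
    """
    ki67_known = ki67 is not None and not (isinstance(ki67, float) and np.isnan(ki67))
    if er == "pos":
        if her2 == "pos" or pr == "neg" or (ki67_known and ki67 >= ki67_cutoff):
            return "LuminalB"
        if pr == "pos" and her2 == "neg" and ki67_known and ki67 < ki67_cutoff:
            return "LuminalA"
        return "Unclassified"
    if er == "neg":
        if pr == "neg" and her2 == "pos":
            return "HER2"
        if pr == "neg" and her2 == "neg":
            return "TNBC"
        return "Unclassified"
    return "Unclassified"


@dataclass(frozen=True)
class CaseControlStatus:
    id: str
    status: str  # case | control | ineligible
    reason: str


def classify_case_control(
    patient_id: str,
    idfs_event: bool,
    idfs_time_years: float,
    followup_years: float,
) -> CaseControlStatus:
    """Classify one patient as case, control, or ineligible."""
    if idfs_time_years < 0 or followup_years < 0:
        raise ValueError(f"patient {patient_id}: negative time")
    if idfs_event:
        if idfs_time_years < CASE_WINDOW_YEARS:
            return CaseControlStatus(patient_id, "case", "iDFS event within 5 years")
        return CaseControlStatus(
            patient_id, "ineligible", "iDFS event at/after 5 years"
        )
    if followup_years >= CASE_WINDOW_YEARS:
        return CaseControlStatus(
            patient_id, "control", "event-free with >= 5 years follow-up"
        )
    return CaseControlStatus(patient_id, "ineligible", "censored before 5 years")


def classify_patients(patients: pd.DataFrame) -> pd.DataFrame:
    """Vector form over a clinical table; adds status and reason columns."""
    out = [
        classify_case_control(
            str(r.id), bool(r.idfs_event), float(r.idfs_time_years), float(r.followup_years)
        )
        for r in patients.itertuples()
    ]
    return pd.DataFrame(
        {
            "id": [s.id for s in out],
            "status": [s.status for s in out],
            "reason": [s.reason for s in out],
        }
    )


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    matching_key: str


def _matching_key(row: pd.Series) -> str:
    if row.get("her2", "unknown") == "unknown":
        return f"ER:{row['er']}|PR:{row['pr']}"
    return str(row["subtype"])


def match_pairs(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    seed: int,
) -> tuple[list[MatchedPair], list[str]]:
    """1:1 individually matched random sampling of controls.

    Cases are processed in a seeded random order; each case draws uniformly
    at random, without replacement, from the not-yet-used controls sharing
    its matching key (molecular subtype; (ER, PR) when the case's HER2 is
    unknown).  Cases with no available control are reported unmatched, not
    fatal.  Fully deterministic given the seed.

    Returns (pairs, unmatched_case_ids).
    """
    if len(cases) == 0:
        raise ValueError("no cases available for matching")
    if len(controls) == 0:
        raise ValueError("no controls available for matching")
    rng = np.random.default_rng(seed)

    control_keys: dict[str, list[str]] = {}
    for _, row in controls.iterrows():
        # controls are indexed under both their subtype and receptor keys so
        # that HER2-unknown cases can draw on receptor combination
        for key in {str(row["subtype"]), f"ER:{row['er']}|PR:{row['pr']}"}:
            control_keys.setdefault(key, []).append(str(row["id"]))

    used: set[str] = set()
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    order = rng.permutation(len(cases))
    for i in order:
        row = cases.iloc[int(i)]
        key = _matching_key(row)
        pool = [c for c in control_keys.get(key, []) if c not in used]
        if not pool:
            unmatched.append(str(row["id"]))
            continue
        pick = pool[int(rng.integers(len(pool)))]
        used.add(pick)
        pairs.append(MatchedPair(str(row["id"]), pick, key))
    return pairs, unmatched


def pairs_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [p.case_id for p in pairs],
            "control_id": [p.control_id for p in pairs],
            "matching_key": [p.matching_key for p in pairs],
        }
    )


def build_matched_dataset(
    patients: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Classify, match, and return the analysis table of matched subjects.

    Returns (matched_patients_with_status, pairs_frame, unmatched_case_ids).
    The matched table carries ``status`` (1 case / 0 control) and ``pair_id``.
    """
    cls = classify_patients(patients)
    merged = patients.merge(cls, on="id")
    cases = merged[merged["status"] == "case"]
    controls = merged[merged["status"] == "control"]
    pairs, unmatched = match_pairs(cases, controls, seed)
    pf = pairs_frame(pairs)
    keep = []
    for k, p in enumerate(pairs):
        keep.append((p.case_id, 1, k))
        keep.append((p.control_id, 0, k))
    sel = pd.DataFrame(keep, columns=["id", "status", "pair_id"])
    out = patients.merge(sel, on="id")
    return out, pf, unmatched
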