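"""Joint Interim Statement (JIS) metabolic-syndrome staging.

Five binary component criteria are evaluated per survey wave:

1. central obesity — waist circumference >= 85 cm (men) / >= 80 cm (women);
2. elevated blood pressure — SBP >= 130 mmHg or DBP >= 85 mmHg, or
   diagnosed and treated hypertension;
3. elevated fasting glucose — FBG >= 5.6 mmol/L or treated hyperglycemia;
4. hypertriglyceridemia — TG >= 1.7 mmol/L;
5. low HDL cholesterol — HDL < 1.03 mmol/L (men) / < 1.29 mmol/L (women),
   or treated for low HDL.

Cut-point boundaries are inclusive (>=) except HDL, which is a strict
less-than, exactly as the criteria are written.  The abnormal-component
count maps to four ordered disease states — FMD (0), MMD (1), SMD (2),
MetS (>= 3) — and the between-wave comparison labels each subject's
transition as forward (strictly worse), reverse (strictly better) or
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ComponentProfile",
    "DiseaseState",
    "MissingCriterionError",
    "classify_components",
    "classify_state",
    "label_transition",
    "stage_cohort",
    "TransitionSummary",
    "cohort_summary",
    "analysis_subset",
]

BIOMARKER_COLUMNS = ("waist_cm", "sbp_mmHg", "dbp_mmHg", "fbg_mmol_L", "tg_mmol_L", "hdl_mmol_L")
TREATMENT_COLUMNS = ("treated_hypertension", "treated_hyperglycemia", "treated_low_hdl")


class MissingCriterionError(ValueError):
    """A component criterion cannot be evaluated for this record."""


class DiseaseState(IntEnum):
    """Ordered severity states; the integer order drives transition labels."""

    FMD = 0  # free of metabolic disorder: no abnormal component
    MMD = 1  # mild: one abnormal component
    SMD = 2  # severe: two abnormal components
    MetS = 3  # metabolic syndrome: three or more


@dataclass(frozen=True)
class ComponentProfile:
    central_obesity: bool
    hypertension: bool
    high_fasting_glucose: bool
    hypertriglyceridemia: bool
    low_hdl: bool

    @property
    def abnormal_count(self) -> int:
        return sum(
            (
                self.central_obesity,
                self.hypertension,
                self.high_fasting_glucose,
                self.hypertriglyceridemia,
                self.low_hdl,
            )
        )


def _present(x) -> bool:
    return x is not None and not (isinstance(x, float) and np.isnan(x))


def _truthy(x) -> bool:
    return _present(x) and bool(x)


def classify_components(
    record: Mapping[str, object],
    sex: str | None = None,
) -> ComponentProfile:
    """Evaluate the five JIS criteria for one wave of one subject.

    ``record`` maps the biomarker/treatment column names (see
    ``BIOMARKER_COLUMNS`` / ``TREATMENT_COLUMNS``) to values; ``sex``
    ("male"/"female") may instead be given as ``record["sex"]``.  A
    criterion whose measurement is missing and whose treatment flag (if
    any) is not set raises ``MissingCriterionError`` naming it.
    """
    sex = str(sex if sex is not None else record.get("sex", "")).lower()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    male = sex == "male"

    def need(field: str, criterion: str) -> float:
        value = record.get(field)
        if not _present(value):
            raise MissingCriterionError(
                f"criterion {criterion!r}: missing {field} and no qualifying treatment flag"
            )
        return float(value)

    waist = need("waist_cm", "central_obesity")
    central_obesity = waist >= (85.0 if male else 80.0)

    if _truthy(record.get("treated_hypertension")):
        hypertension = True
    else:
        hypertension = (
            need("sbp_mmHg", "hypertension") >= 130.0
            or need("dbp_mmHg", "hypertension") >= 85.0
        )

    if _truthy(record.get("treated_hyperglycemia")):
        high_fbg = True
    else:
        high_fbg = need("fbg_mmol_L", "high_fasting_glucose") >= 5.6

    high_tg = need("tg_mmol_L", "hypertriglyceridemia") >= 1.7

    if _truthy(record.get("treated_low_hdl")):
        low_hdl = True
    else:
        low_hdl = need("hdl_mmol_L", "low_hdl") < (1.03 if male else 1.29)

    return ComponentProfile(central_obesity, hypertension, high_fbg, high_tg, low_hdl)


def classify_state(profile: ComponentProfile | int) -> DiseaseState:
    """Map an abnormal-component count to the four-state staging."""
    count = profile.abnormal_count if isinstance(profile, ComponentProfile) else int(profile)
    if count < 0 or count > 5:
        raise ValueError(f"component count must be in 0..5, got {count}")
    return DiseaseState(min(count, 3))


def label_transition(baseline: DiseaseState, followup: DiseaseState) -> str:
    """'forward' if strictly worse at follow-up, 'reverse' if strictly better."""
    if followup > baseline:
        return "forward"
    if followup < baseline:
        return "reverse"
    return "unchanged"


def stage_cohort(data: pd.DataFrame, waves: tuple[str, str] = ("baseline", "followup")) -> pd.DataFrame:
    """Stage every subject at both waves and label the transition.

    Expects a ``sex`` column plus, per wave, biomarker columns prefixed
    ``<wave>_`` (e.g. ``baseline_waist_cm``) and the wave-invariant
    treatment flags.  Subjects with an unevaluable criterion are dropped
    (complete-case), and the returned frame adds ``<wave>_components``,
    ``<wave>_state`` and ``transition`` columns.
    """
    rows = []
    for _, rec in data.iterrows():
        out = dict(rec)
        try:
            states = {}
            for wave in waves:
                wave_rec = {
                    col: rec.get(f"{wave}_{col}") for col in BIOMARKER_COLUMNS
                }
                wave_rec.update({col: rec.get(col) for col in TREATMENT_COLUMNS})
                profile = classify_components(wave_rec, sex=rec["sex"])
                states[wave] = classify_state(profile)
                out[f"{wave}_components"] = profile.abnormal_count
                out[f"{wave}_state"] = states[wave].name
        except MissingCriterionError:
            continue
        out["transition"] = label_transition(states[waves[0]], states[waves[1]])
        rows.append(out)
    return pd.DataFrame(rows).reset_index(drop=True)


@dataclass(frozen=True)
class TransitionSummary:
    """Cohort-level transition accounting between two waves."""

    n: int
    baseline_mets: int
    followup_mets: int
    new_mets_cases: int
    baseline_non_mets: int
    unchanged: int
    forward: int
    reverse: int

    @property
    def changes(self) -> int:
        return self.forward + self.reverse

    @property
    def cumulative_incidence_pct(self) -> float:
        """New MetS cases per 100 baseline non-MetS subjects."""
        return 100.0 * self.new_mets_cases / self.baseline_non_mets

    @property
    def unchanged_pct(self) -> float:
        return 100.0 * self.unchanged / self.n

    @property
    def forward_pct_of_changes(self) -> float | None:
        return 100.0 * self.forward / self.changes if self.changes else None

    @property
    def reverse_pct_of_changes(self) -> float | None:
        return 100.0 * self.reverse / self.changes if self.changes else None

    @classmethod
    def from_counts(
        cls,
        n: int,
        baseline_mets: int,
        followup_mets: int,
        new_mets_cases: int,
        unchanged: int,
        forward: int,
        reverse: int,
    ) -> "TransitionSummary":
        return cls(
            n=n,
            baseline_mets=baseline_mets,
            followup_mets=followup_mets,
            new_mets_cases=new_mets_cases,
            baseline_non_mets=n - baseline_mets,
            unchanged=unchanged,
            forward=forward,
            reverse=reverse,
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "baseline_mets": self.baseline_mets,
            "followup_mets": self.followup_mets,
            "new_mets_cases": self.new_mets_cases,
            "baseline_non_mets": self.baseline_non_mets,
            "cumulative_incidence_pct": self.cumulative_incidence_pct,
            "unchanged": self.unchanged,
            "unchanged_pct": self.unchanged_pct,
            "forward": self.forward,
            "forward_pct_of_changes": self.forward_pct_of_changes,
            "reverse": self.reverse,
            "reverse_pct_of_changes": self.reverse_pct_of_changes,
        }


def cohort_summary(staged: pd.DataFrame) -> TransitionSummary:
    """Transition accounting over a staged cohort (both waves required)."""
    required = {"baseline_state", "followup_state", "transition"}
    missing = required - set(staged.columns)
    if missing:
        raise ValueError(f"staged cohort is missing columns: {sorted(missing)}")
    base_mets = staged["baseline_state"].eq("MetS")
    fu_mets = staged["followup_state"].eq("MetS")
    return TransitionSummary.from_counts(
        n=len(staged),
        baseline_mets=int(base_mets.sum()),
        followup_mets=int(fu_mets.sum()),
        new_mets_cases=int((~base_mets & fu_mets).sum()),
        unchanged=int(staged["transition"].eq("unchanged").sum()),
        forward=int(staged["transition"].eq("forward").sum()),
        reverse=int(staged["transition"].eq("reverse").sum()),
    )


def analysis_subset(staged: pd.DataFrame, model: str) -> pd.DataFrame:
    """Rows eligible for one of the two outcome models.

    The progression model uses subjects at risk of progressing (baseline
    state below MetS) whose transition is unchanged or forward; the
    recovery model uses subjects at risk of recovering (baseline state
    above FMD) whose transition is unchanged or reverse.  Movers in the
    opposite direction are excluded from that model.  Adds the binary
    outcome column (``progression`` or ``recovery``).
    """
    if model == "progression":
        mask = staged["baseline_state"].ne("MetS") & staged["transition"].isin(
            ["unchanged", "forward"]
        )
        out = staged[mask].copy()
        out["progression"] = np.where(
            out["transition"].eq("forward"), "forward", "unchanged"
        )
    elif model == "recovery":
        mask = staged["baseline_state"].ne("FMD") & staged["transition"].isin(
            ["unchanged", "reverse"]
        )
        out = staged[mask].copy()
        out["recovery"] = np.where(
            out["transition"].eq("reverse"), "reverse", "unchanged"
        )
    else:
        raise ValueError("model must be 'progression' or 'recovery'")
    return out.reset_index(drop=True)
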