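"""Synthetic longitudinal cohorts with the statistical structure the
analysis assumes.

``sample_from_network`` draws iid forward samples from any discrete
Bayesian network.  ``generate_cohort`` emulates a two-wave ageing-cohort
biomarker dataset: categorical covariates are drawn from the published
prior distributions (with gender -> hyperuricemia and
age/exercise -> BMI dependence as in the published network), baseline
biomarkers come from sex-specific log-normal distributions shifted on
the log scale by covariate effects, the between-wave transition is drawn
from the published outcome CPTs, and follow-up biomarkers are then
constructed to realize the drawn transition under the JIS criteria.

Progression and recovery are competing moves: each subject draws an
independent progression propensity (Table-style CPT given
hyperuricemia and BMI, only if below MetS at baseline) and recovery
propensity (given HbA1c and BMI, only if above FMD); simultaneous moves
are rejected, which leaves each CPT exactly preserved within its own
analysis population (at-risk subjects, opposite-direction movers
excluded).

Biomarker locations, spreads and effect sizes are synthetic plumbing:
they are tuned only so each component's prevalence lands in a plausible
10-50% band, and nothing downstream depends on their specific values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .fixtures import (
    AGE_LEVELS,
    BMI_LEVELS,
    EXERCISE_LEVELS,
    GENDER_LEVELS,
    PROGRESSION_MARGINALS,
    PROGRESSION_OUTCOME_CPT,
    RECOVERY_OUTCOME_CPT,
    build_published_fixture,
)
from .network import DiscreteBayesNet

__all__ = ["CohortConfig", "sample_from_network", "generate_cohort"]


def sample_from_network(net: DiscreteBayesNet, n: int, seed: int = 0) -> pd.DataFrame:
    """n iid forward samples in topological order; reproducible given seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}
    for node in net.dag.topological_order():
        arr = net.cpt_array(node)
        r = net.variable(node).cardinality
        parents = net.cpts[node].parents
        flat = arr.reshape(-1, r)
        if parents:
            dims = [net.variable(p).cardinality for p in parents]
            row_idx = np.ravel_multi_index([codes[p] for p in parents], dims)
        else:
            row_idx = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(flat, axis=1)
        u = rng.random(n)
        codes[node] = (u[:, None] > cum[row_idx]).sum(axis=1)
    out = {}
    for name in net.names:
        levels = np.array(net.variable(name).levels)
        out[name] = levels[codes[name]] if n else np.array([], dtype=object)
    return pd.DataFrame(out, columns=list(net.names))


# ---------------------------------------------------------------------------
# biomarker model (synthetic plumbing)

#: sex-specific log-normal parameters: (median, sigma on the log scale)
_BIOMARKER_BASE = {
    "waist_cm": {"male": (81.5, 0.09), "female": (76.0, 0.10)},
    "sbp_mmHg": {"male": (118.0, 0.12), "female": (118.0, 0.12)},
    "dbp_mmHg": {"male": (75.0, 0.11), "female": (75.0, 0.11)},
    "fbg_mmol_L": {"male": (5.2, 0.12), "female": (5.2, 0.12)},
    "tg_mmol_L": {"male": (1.30, 0.45), "female": (1.30, 0.45)},
    "hdl_mmol_L": {"male": (1.18, 0.25), "female": (1.42, 0.25)},
}

#: additive shifts on the log scale: covariate level -> biomarker -> shift
_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("bmi", "overweight"): {
        "waist_cm": 0.10, "tg_mmol_L": 0.25, "fbg_mmol_L": 0.05,
        "hdl_mmol_L": -0.10, "sbp_mmHg": 0.04,
    },
    ("bmi", "thin"): {"waist_cm": -0.12, "tg_mmol_L": -0.10, "hdl_mmol_L": 0.05},
    ("hyperuricemia", "yes"): {"tg_mmol_L": 0.15},
    ("high_hba1c", "yes"): {"fbg_mmol_L": 0.12},
    ("age", "55-64"): {"sbp_mmHg": 0.03},
    ("age", "65+"): {"sbp_mmHg": 0.06, "dbp_mmHg": 0.02},
    ("exercise", "little"): {"waist_cm": 0.03, "tg_mmol_L": 0.05},
    ("exercise", "frequently"): {"waist_cm": -0.02, "hdl_mmol_L": 0.03},
}

#: JIS cut points; HDL is a strict less-than, the rest are >=
_WAIST_CUT = {"male": 85.0, "female": 80.0}
_HDL_CUT = {"male": 1.03, "female": 1.29}
_SBP_CUT, _DBP_CUT, _FBG_CUT, _TG_CUT = 130.0, 85.0, 5.6, 1.7


@dataclass
class CohortConfig:
    """Generating parameters for the synthetic two-wave cohort.

    Covariate marginals default to the published prior distributions;
    marginals the tables do not print (smoke, drink, functional loss)
    are plausible inventions.  The transition CPTs default to the
    published conditional tables.
    """

    n: int = 20_000
    seed: int = 0
    gender: tuple[float, float] = PROGRESSION_MARGINALS["gender"]
    age: tuple[float, float, float] = PROGRESSION_MARGINALS["age"]
    exercise: tuple[float, float, float] = PROGRESSION_MARGINALS["exercise"]
    smoke_prevalence: float = 0.28
    drink_prevalence: float = 0.24
    functional_loss_prevalence: float = 0.20
    high_hba1c_prevalence: float = 0.0728
    treated_hypertension_prevalence: float = 0.10
    treated_hyperglycemia_prevalence: float = 0.05
    treated_low_hdl_prevalence: float = 0.02
    progression_cpt: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(PROGRESSION_OUTCOME_CPT)
    )
    recovery_cpt: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(RECOVERY_OUTCOME_CPT)
    )
    max_regeneration_passes: int = 50

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("gender", "age", "exercise"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} marginal is not a probability vector")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["progression_cpt"] = {"|".join(k): list(v) for k, v in self.progression_cpt.items()}
        d["recovery_cpt"] = {"|".join(k): list(v) for k, v in self.recovery_cpt.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("progression_cpt", "recovery_cpt"):
            if key in d and d[key] and isinstance(next(iter(d[key])), str):
                d[key] = {tuple(k.split("|")): tuple(v) for k, v in d[key].items()}
        for key in ("gender", "age", "exercise"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw_levels(rng: np.random.Generator, probs, levels, n: int) -> np.ndarray:
    codes = rng.choice(len(levels), size=n, p=np.asarray(probs, dtype=float))
    return np.asarray(levels, dtype=object)[codes]


def _covariates(rng: np.random.Generator, cfg: CohortConfig, n: int) -> pd.DataFrame:
    """Covariate block; hyperuricemia|gender and BMI|age,exercise follow the
    published-network fixture CPTs so their marginals match the published priors."""
    net = build_published_fixture("progression")
    df = pd.DataFrame(
        {
            "sex": _draw_levels(rng, cfg.gender, GENDER_LEVELS, n),
            "age_group": _draw_levels(rng, cfg.age, AGE_LEVELS, n),
            "exercise": _draw_levels(rng, cfg.exercise, EXERCISE_LEVELS, n),
        }
    )
    hyper_cpt = net.cpts["hyperuricemia"]
    p_yes = np.where(
        df["sex"].to_numpy() == "male",
        hyper_cpt.row(("male",))[1],
        hyper_cpt.row(("female",))[1],
    )
    df["hyperuricemia"] = np.where(rng.random(n) < p_yes, "yes", "no")
    bmi_cpt = net.cpts["bmi"]
    bmi = np.empty(n, dtype=object)
    for a in AGE_LEVELS:
        for e in EXERCISE_LEVELS:
            mask = (df["age_group"].to_numpy() == a) & (df["exercise"].to_numpy() == e)
            k = int(mask.sum())
            if k:
                bmi[mask] = _draw_levels(rng, bmi_cpt.row((a, e)), BMI_LEVELS, k)
    df["bmi_level"] = bmi
    df["smoke"] = np.where(rng.random(n) < cfg.smoke_prevalence, "yes", "no")
    df["drink"] = np.where(rng.random(n) < cfg.drink_prevalence, "yes", "no")
    df["functional_loss"] = np.where(
        rng.random(n) < cfg.functional_loss_prevalence, "yes", "no"
    )
    df["high_hba1c"] = np.where(rng.random(n) < cfg.high_hba1c_prevalence, "yes", "no")
    df["treated_hypertension"] = rng.random(n) < cfg.treated_hypertension_prevalence
    df["treated_hyperglycemia"] = rng.random(n) < cfg.treated_hyperglycemia_prevalence
    df["treated_low_hdl"] = rng.random(n) < cfg.treated_low_hdl_prevalence
    return df


def _baseline_biomarkers(rng: np.random.Generator, cov: pd.DataFrame) -> pd.DataFrame:
    n = len(cov)
    male = cov["sex"].to_numpy() == "male"
    out = {}
    for marker, by_sex in _BIOMARKER_BASE.items():
        mu = np.where(male, np.log(by_sex["male"][0]), np.log(by_sex["female"][0]))
        sigma = np.where(male, by_sex["male"][1], by_sex["female"][1])
        shift = np.zeros(n)
        for (covariate, level), effects in _EFFECTS.items():
            col = {"bmi": "bmi_level", "age": "age_group"}.get(covariate, covariate)
            if marker in effects:
                shift += np.where(cov[col].to_numpy() == level, effects[marker], 0.0)
        out[marker] = np.exp(mu + shift + sigma * rng.standard_normal(n))
    return pd.DataFrame(out)


_COMPONENTS = ("central_obesity", "hypertension", "high_fasting_glucose", "hypertriglyceridemia", "low_hdl")


def _component_flags(bio: pd.DataFrame, cov: pd.DataFrame) -> np.ndarray:
    male = cov["sex"].to_numpy() == "male"
    waist_cut = np.where(male, _WAIST_CUT["male"], _WAIST_CUT["female"])
    hdl_cut = np.where(male, _HDL_CUT["male"], _HDL_CUT["female"])
    flags = np.column_stack(
        [
            bio["waist_cm"].to_numpy() >= waist_cut,
            (bio["sbp_mmHg"].to_numpy() >= _SBP_CUT)
            | (bio["dbp_mmHg"].to_numpy() >= _DBP_CUT)
            | cov["treated_hypertension"].to_numpy(),
            (bio["fbg_mmol_L"].to_numpy() >= _FBG_CUT)
            | cov["treated_hyperglycemia"].to_numpy(),
            bio["tg_mmol_L"].to_numpy() >= _TG_CUT,
            (bio["hdl_mmol_L"].to_numpy() < hdl_cut)
            | cov["treated_low_hdl"].to_numpy(),
        ]
    )
    return flags


def _locked_flags(cov: pd.DataFrame) -> np.ndarray:
    """Components forced true by treatment regardless of measurements."""
    n = len(cov)
    locked = np.zeros((n, 5), dtype=bool)
    locked[:, 1] = cov["treated_hypertension"].to_numpy()
    locked[:, 2] = cov["treated_hyperglycemia"].to_numpy()
    locked[:, 4] = cov["treated_low_hdl"].to_numpy()
    return locked


def _cpt_prob(cpt: Mapping[tuple[str, str], tuple[float, float]], a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros(len(a))
    for (ka, kb), (p_stay, p_move) in cpt.items():
        out[(a == ka) & (b == kb)] = p_move / (p_stay + p_move)
    return out


def _draw_transition(
    rng: np.random.Generator, cfg: CohortConfig, cov: pd.DataFrame, state0: np.ndarray
) -> np.ndarray:
    """Competing progression/recovery moves with simultaneous-move rejection."""
    n = len(cov)
    p_f = _cpt_prob(cfg.progression_cpt, cov["hyperuricemia"].to_numpy(), cov["bmi_level"].to_numpy())
    p_r = _cpt_prob(cfg.recovery_cpt, cov["high_hba1c"].to_numpy(), cov["bmi_level"].to_numpy())
    p_f = np.where(state0 < 3, p_f, 0.0)
    p_r = np.where(state0 > 0, p_r, 0.0)
    denom = 1.0 - p_f * p_r
    f = p_f * (1.0 - p_r) / denom
    r = p_r * (1.0 - p_f) / denom
    u = rng.random(n)
    return np.where(u < f, "forward", np.where(u < f + r, "reverse", "unchanged")).astype(object)


def _target_counts(
    rng: np.random.Generator, transition: np.ndarray, count0: np.ndarray, state0: np.ndarray
) -> np.ndarray:
    """Follow-up component count realizing the drawn transition."""
    n = len(transition)
    target = count0.copy()
    fwd = transition == "forward"
    new_state = state0 + 1
    # forward into MetS draws 3-5 components; below MetS the count is the state
    mets_extra = rng.choice([3, 4, 5], size=n, p=[0.6, 0.3, 0.1])
    target[fwd] = np.where(new_state[fwd] >= 3, mets_extra[fwd], new_state[fwd])
    rev = transition == "reverse"
    target[rev] = state0[rev] - 1
    return target


def _follow_up_flags(
    rng: np.random.Generator,
    flags0: np.ndarray,
    locked: np.ndarray,
    target: np.ndarray,
    transition: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip unlocked components to hit the target count; returns (flags, ok)."""
    n, flags1 = len(target), flags0.copy()
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        if transition[i] == "unchanged":
            continue  # keep the baseline component profile
        have = int(flags1[i].sum())
        want = int(target[i])
        if want < int(locked[i].sum()):
            ok[i] = False
            continue
        if want > have:
            candidates = np.flatnonzero(~flags1[i])
            turn_on = rng.choice(candidates, size=want - have, replace=False)
            flags1[i, turn_on] = True
        elif want < have:
            candidates = np.flatnonzero(flags1[i] & ~locked[i])
            if len(candidates) < have - want:
                ok[i] = False
                continue
            turn_off = rng.choice(candidates, size=have - want, replace=False)
            flags1[i, turn_off] = False
    return flags1, ok


def _biomarkers_from_flags(
    rng: np.random.Generator, cov: pd.DataFrame, flags: np.ndarray
) -> pd.DataFrame:
    """Draw biomarkers on the required side of each JIS cut point.

    Values are the cut point scaled by a half-normal factor on the log
    scale (with a small margin on the 'normal' side so >=/< boundaries
    are respected); for treated components the measurement is drawn from
    the normal side, since treatment alone qualifies the component.
    """
    n = len(cov)
    male = cov["sex"].to_numpy() == "male"

    def split(cut, flag, sigma_hi, sigma_lo, strict_below=False):
        hi = cut * np.exp(np.abs(rng.standard_normal(n)) * sigma_hi + 1e-4)
        lo = cut * np.exp(-np.abs(rng.standard_normal(n)) * sigma_lo - 1e-4)
        if strict_below:
            hi, lo = lo, hi  # abnormal side is below the cut
        return np.where(flag, hi, lo)

    waist_cut = np.where(male, _WAIST_CUT["male"], _WAIST_CUT["female"])
    hdl_cut = np.where(male, _HDL_CUT["male"], _HDL_CUT["female"])
    treated_ht = cov["treated_hypertension"].to_numpy()
    treated_glu = cov["treated_hyperglycemia"].to_numpy()
    treated_hdl = cov["treated_low_hdl"].to_numpy()

    out = pd.DataFrame(
        {
            "waist_cm": split(waist_cut, flags[:, 0], 0.05, 0.06),
            "sbp_mmHg": split(_SBP_CUT, flags[:, 1] & ~treated_ht, 0.07, 0.06),
            "dbp_mmHg": split(_DBP_CUT, np.zeros(n, dtype=bool), 0.05, 0.07),
            "fbg_mmol_L": split(_FBG_CUT, flags[:, 2] & ~treated_glu, 0.10, 0.06),
            "tg_mmol_L": split(_TG_CUT, flags[:, 3], 0.30, 0.25),
            "hdl_mmol_L": split(hdl_cut, flags[:, 4] & ~treated_hdl, 0.12, 0.12, strict_below=True),
        }
    )
    return out


def generate_cohort(config: CohortConfig | None = None, **kwargs) -> pd.DataFrame:
    """Simulate a two-wave cohort; see the module docstring for the model.

    Subjects whose drawn transition cannot be realized (treatment flags
    lock more components than the target state allows) are regenerated
    from fresh randomness; the returned frame classifies consistently
    with the drawn ``transition`` column by construction.
    """
    cfg = config or CohortConfig(**kwargs)
    if config is not None and kwargs:
        raise ValueError("pass either a CohortConfig or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)

    remaining = cfg.n
    chunks: list[pd.DataFrame] = []
    for _ in range(cfg.max_regeneration_passes):
        if remaining == 0:
            break
        cov = _covariates(rng, cfg, remaining)
        bio0 = _baseline_biomarkers(rng, cov)
        flags0 = _component_flags(bio0, cov)
        locked = _locked_flags(cov)
        count0 = flags0.sum(axis=1)
        state0 = np.minimum(count0, 3)
        transition = _draw_transition(rng, cfg, cov, state0)
        target = _target_counts(rng, transition, count0, state0)
        flags1, ok = _follow_up_flags(rng, flags0, locked, target, transition)
        bio1 = _biomarkers_from_flags(rng, cov, flags1)

        good = cov[ok].reset_index(drop=True)
        frame = pd.concat(
            [
                good,
                bio0[ok].reset_index(drop=True).add_prefix("baseline_"),
                bio1[ok].reset_index(drop=True).add_prefix("followup_"),
            ],
            axis=1,
        )
        frame["transition"] = transition[ok]
        chunks.append(frame)
        remaining -= int(ok.sum())
    if remaining:
        raise RuntimeError(
            f"could not realize transitions for {remaining} subjects after "
            f"{cfg.max_regeneration_passes} regeneration passes"
        )
    out = pd.concat(chunks, ignore_index=True)
    out.insert(0, "id", np.arange(1, cfg.n + 1))
    return out
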