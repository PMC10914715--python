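"""The two published metabolic-syndrome networks as ready-made fixtures.

The progression network has roots gender, age and exercise, with arcs
gender -> hyperuricemia, age -> BMI, exercise -> BMI and the two direct
influences hyperuricemia -> progression, BMI -> progression.  The
recovery network has arcs gender -> BMI, exercise -> BMI,
BMI -> recovery and high HbA1c -> recovery.  Root marginals and the
outcome CPTs are the published estimates (transcribed to 4 decimal
probabilities from percent tables); one recovery-outcome row whose
printed percentages sum to 100.30 is renormalized to 1.

The published tables do not include the intermediate CPTs
P(hyperuricemia | gender) and P(BMI | age/gender, exercise).  These are
reconstructed so the implied marginals of hyperuricemia and BMI equal
the published priors exactly: the BMI rows are zero-sum tilts of the
published BMI marginal with effect scores centred under the root
marginals (older age / less exercise / male shift mass toward
overweight), and the hyperuricemia CPT gives men twice the risk of
women while preserving the published 8.41% prevalence.  Effect
magnitudes here are synthetic plumbing; inference on the outcome is
insensitive to them because the outcome depends on its parents only.
"""

from __future__ import annotations

import numpy as np

from .network import CategoricalVariable, Cpt, Dag, DiscreteBayesNet

__all__ = [
    "PROGRESSION_OUTCOME_CPT",
    "RECOVERY_OUTCOME_CPT",
    "PROGRESSION_MARGINALS",
    "RECOVERY_MARGINALS",
    "build_published_fixture",
]

GENDER_LEVELS = ("female", "male")
AGE_LEVELS = ("40-54", "55-64", "65+")
EXERCISE_LEVELS = ("frequently", "occasionally", "little")
BMI_LEVELS = ("normal", "thin", "overweight")  # overweight = overweight or obesity
YESNO = ("no", "yes")

#: P(progression status | hyperuricemia, BMI level): (unchanged, forward)
PROGRESSION_OUTCOME_CPT = {
    ("no", "normal"): (0.7061, 0.2939),
    ("no", "thin"): (0.6573, 0.3427),
    ("no", "overweight"): (0.6200, 0.3800),
    ("yes", "normal"): (0.4500, 0.5500),
    ("yes", "thin"): (0.9468, 0.0532),
    ("yes", "overweight"): (0.2801, 0.7199),
}

#: P(recovery status | high HbA1c, BMI level): (unchanged, reverse).
#: The (yes, normal) row sums to 1.0030 as printed and is renormalized.
RECOVERY_OUTCOME_CPT = {
    ("no", "normal"): (0.6567, 0.3433),
    ("no", "thin"): (0.5435, 0.4565),
    ("no", "overweight"): (0.6908, 0.3092),
    ("yes", "normal"): (0.7533, 0.2497),
    ("yes", "thin"): (0.7335, 0.2665),
    ("yes", "overweight"): (0.8763, 0.1237),
}

#: Published prior distributions (progression analysis population).
PROGRESSION_MARGINALS = {
    "gender": (0.6294, 0.3706),
    "age": (0.3632, 0.3927, 0.2441),
    "exercise": (0.3015, 0.3852, 0.3133),
    "bmi": (0.4791, 0.0572, 0.4637),
    "hyperuricemia": (0.9159, 0.0841),  # (no, yes)
}

#: Published prior distributions (recovery analysis population).
RECOVERY_MARGINALS = {
    "gender": (0.6611, 0.3389),
    "exercise": (0.2957, 0.3816, 0.3227),
    "bmi": (0.5384, 0.0701, 0.3915),
    "high_hba1c": (0.9272, 0.0728),  # (no, yes)
}

# synthetic effect magnitudes for the reconstructed BMI tilts,
# per unit of centred score, over (normal, thin, overweight)
_AGE_TILT = np.array([-0.040, 0.008, 0.032])
_EXERCISE_TILT = np.array([-0.050, -0.005, 0.055])
_GENDER_TILT = np.array([-0.060, -0.010, 0.070])


def _centred_scores(marginal: tuple[float, ...]) -> np.ndarray:
    codes = np.arange(len(marginal), dtype=float)
    return codes - float(np.dot(marginal, codes))


def _tilted_bmi_cpt(
    base: tuple[float, ...],
    parents: dict[str, tuple[tuple[float, ...], np.ndarray]],
) -> dict[tuple[str, ...], np.ndarray]:
    """Rows = base + sum of zero-sum tilts; marginal over parents = base."""
    names = list(parents)
    levels = {
        "gender": GENDER_LEVELS,
        "age": AGE_LEVELS,
        "exercise": EXERCISE_LEVELS,
    }
    scores = {p: _centred_scores(marg) for p, (marg, _) in parents.items()}
    rows: dict[tuple[str, ...], np.ndarray] = {}
    import itertools

    for combo_idx in itertools.product(*(range(len(levels[p])) for p in names)):
        row = np.array(base, dtype=float)
        for p, i in zip(names, combo_idx):
            row = row + scores[p][i] * parents[p][1]
        if np.any(row <= 0) or np.any(row >= 1):  # pragma: no cover - static config
            raise ValueError("tilt magnitudes push a BMI row out of (0,1)")
        rows[tuple(levels[p][i] for p, i in zip(names, combo_idx))] = row
    return rows


def _hyperuricemia_cpt() -> dict[tuple[str, ...], tuple[float, float]]:
    """Male risk = 2x female risk, preserving the published prevalence."""
    p_female, p_male = PROGRESSION_MARGINALS["gender"]
    prevalence = PROGRESSION_MARGINALS["hyperuricemia"][1]
    f = prevalence / (p_female + 2.0 * p_male)
    m = 2.0 * f
    return {("female",): (1.0 - f, f), ("male",): (1.0 - m, m)}


def build_published_fixture(which: str) -> DiscreteBayesNet:
    """Build the published progression or recovery network.

    ``which`` is ``"progression"`` or ``"recovery"``.  The returned
    network passes ``validate_network`` and reproduces the published
    hyperuricemia / BMI / HbA1c marginals to within 1e-6.
    """
    if which == "progression":
        m = PROGRESSION_MARGINALS
        variables = [
            CategoricalVariable("gender", GENDER_LEVELS),
            CategoricalVariable("age", AGE_LEVELS),
            CategoricalVariable("exercise", EXERCISE_LEVELS),
            CategoricalVariable("hyperuricemia", YESNO),
            CategoricalVariable("bmi", BMI_LEVELS),
            CategoricalVariable("progression", ("unchanged", "forward")),
        ]
        dag = Dag(
            [v.name for v in variables],
            [
                ("gender", "hyperuricemia"),
                ("age", "bmi"),
                ("exercise", "bmi"),
                ("hyperuricemia", "progression"),
                ("bmi", "progression"),
            ],
        )
        bmi_rows = _tilted_bmi_cpt(
            m["bmi"],
            {"age": (m["age"], _AGE_TILT), "exercise": (m["exercise"], _EXERCISE_TILT)},
        )
        cpts = {
            "gender": Cpt("gender", (), {(): m["gender"]}),
            "age": Cpt("age", (), {(): m["age"]}),
            "exercise": Cpt("exercise", (), {(): m["exercise"]}),
            "hyperuricemia": Cpt("hyperuricemia", ("gender",), _hyperuricemia_cpt()),
            "bmi": Cpt("bmi", ("age", "exercise"), bmi_rows),
            "progression": Cpt(
                "progression", ("hyperuricemia", "bmi"), PROGRESSION_OUTCOME_CPT
            ),
        }
        return DiscreteBayesNet(variables=variables, dag=dag, cpts=cpts)
    if which == "recovery":
        m = RECOVERY_MARGINALS
        variables = [
            CategoricalVariable("gender", GENDER_LEVELS),
            CategoricalVariable("exercise", EXERCISE_LEVELS),
            CategoricalVariable("high_hba1c", YESNO),
            CategoricalVariable("bmi", BMI_LEVELS),
            CategoricalVariable("recovery", ("unchanged", "reverse")),
        ]
        dag = Dag(
            [v.name for v in variables],
            [
                ("gender", "bmi"),
                ("exercise", "bmi"),
                ("high_hba1c", "recovery"),
                ("bmi", "recovery"),
            ],
        )
        bmi_rows = _tilted_bmi_cpt(
            m["bmi"],
            {
                "gender": (m["gender"], _GENDER_TILT),
                "exercise": (m["exercise"], _EXERCISE_TILT),
            },
        )
        cpts = {
            "gender": Cpt("gender", (), {(): m["gender"]}),
            "exercise": Cpt("exercise", (), {(): m["exercise"]}),
            "high_hba1c": Cpt("high_hba1c", (), {(): m["high_hba1c"]}),
            "bmi": Cpt("bmi", ("gender", "exercise"), bmi_rows),
            "recovery": Cpt(
                "recovery", ("high_hba1c", "bmi"), RECOVERY_OUTCOME_CPT, normalize=True
            ),
        }
        return DiscreteBayesNet(variables=variables, dag=dag, cpts=cpts)
    raise ValueError("which must be 'progression' or 'recovery'")
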