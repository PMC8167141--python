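"""Population demographics from predicted age and sex.

Applies life-history category boundaries used for killer whale
populations: juveniles up to the sex-specific maturation age (9 y in
females, 13 y in males), adults to 40 y, and post-reproductive females /
aged males beyond 40 y (boundaries strict: an animal exactly at a cut
stays in the younger category).  Two exact tests accompany the summary:

* a one-sided exact binomial test of the sex ratio against 1:1, toward
  the majority sex;
* the probability of observing zero individuals in a class (e.g., females
  over 40) whose population proportion is known from a reference
  population — the binomial mass at zero, (1 - p)^n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_category",
    "sex_ratio_test",
    "expected_count_test",
    "DemographicsSummary",
    "summarize_population",
]

FEMALE_ADULT_AGE = 9.0
MALE_ADULT_AGE = 13.0
OLD_AGE = 40.0


def assign_category(age: float, sex: str) -> str:
    """Life-history category for one individual.

    Females: juvenile (<= 9 y), adult female (> 9 to <= 40), then
    post-reproductive female.  Males: juvenile (<= 13 y), adult male
    (> 13 to <= 40), then aged male.  Unknown sex yields "unclassified".
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if sex == "F":
        if age <= FEMALE_ADULT_AGE:
            return "juvenile"
        return "adult female" if age <= OLD_AGE else "post-reproductive female"
    if sex == "M":
        if age <= MALE_ADULT_AGE:
            return "juvenile"
        return "adult male" if age <= OLD_AGE else "aged male"
    return "unclassified"


def sex_ratio_test(n_male: int, n_female: int) -> float:
    """One-sided exact binomial p of the skew toward the majority sex.

    p = P(X >= max(n_male, n_female)) under Binomial(n, 1/2); symmetric
    in its arguments.
    """
    n = n_male + n_female
    if n < 1:
        raise ValueError("need at least one sexed individual")
    k = max(n_male, n_female)
    return float(stats.binom.sf(k - 1, n, 0.5))


def expected_count_test(n: int, reference_prop: float) -> dict:
    """Expected class count in a sample of n and the chance of seeing none.

    ``expected = n * reference_prop``; ``p_zero = (1 - reference_prop)^n``
    is the exact binomial probability that the class is absent from the
    sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < reference_prop < 1:
        raise ValueError("reference_prop must be in (0, 1)")
    return {
        "expected_count": n * reference_prop,
        "p_zero": (1.0 - reference_prop) ** n,
    }


@dataclass
class DemographicsSummary:
    individuals: pd.DataFrame  # individual_id, age, sex, category
    category_percentages: pd.Series
    n_male: int
    n_female: int
    sex_ratio_p: float
    old_female_expected: float | None = None
    old_female_p_zero: float | None = None


def summarize_population(
    ages, sexes, ids=None, reference_old_female_prop: float | None = None
) -> DemographicsSummary:
    """Demographic chart for a set of individuals with predicted age/sex.

    Percentages are over sexed (classified) individuals and sum to 100.
    If ``reference_old_female_prop`` is given, the expected number of
    females over 40 and the probability of observing zero are computed
    against that reference proportion (denominator: all sexed
    individuals).
    """
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes, dtype=object)
    if ids is None:
        ids = [f"ind{i}" for i in range(len(ages))]
    cats = [assign_category(a, s) for a, s in zip(ages, sexes)]
    df = pd.DataFrame({"individual_id": ids, "age": ages, "sex": sexes, "category": cats})
    classified = df[df["category"] != "unclassified"]
    pct = 100.0 * classified["category"].value_counts() / len(classified)
    n_male = int((classified["sex"] == "M").sum())
    n_female = int((classified["sex"] == "F").sum())
    summary = DemographicsSummary(
        individuals=df,
        category_percentages=pct,
        n_male=n_male,
        n_female=n_female,
        sex_ratio_p=sex_ratio_test(n_male, n_female),
    )
    if reference_old_female_prop is not None:
        res = expected_count_test(len(classified), reference_old_female_prop)
        summary.old_female_expected = res["expected_count"]
        summary.old_female_p_zero = res["p_zero"]
    return summary
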