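"""Published reference tables and internal-arithmetic validation.

The original field deployment of this pipeline published a per-class metric
table for the behaviour classifier and a daily behaviour-budget table. The
field data themselves are not public, but the printed tables obey exact
arithmetic relationships (macro rows are unweighted class means, F1 is the
harmonic mean of precision and recall, percent-of-day follows from minutes
under 1440-min rescaling). This module stores those published rows as input
constants and re-derives the relationships, both as a self-check of the
metric code and as a validation checklist for any generated report bundle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Published per-class test-set metrics of the deployed Random-Forest model
#: (balanced accuracy in the "accuracy" column; prevalence = test windows).
REFERENCE_CLASS_METRICS = pd.DataFrame(
    [
        ("Bellowing", 0.791667, 0.142857, 0.242038, 0.571197, 133),
        ("Climbing", 0.780275, 0.788146, 0.784191, 0.885394, 793),
        ("Feeding", 0.762519, 0.834025, 0.796671, 0.900923, 1205),
        ("Grooming", 0.734861, 0.683409, 0.708202, 0.824861, 1314),
        ("Still", 0.998971, 0.95334, 0.975622, 0.976558, 2036),
        ("In-tree Movement", 0.765428, 0.837678, 0.799925, 0.880148, 2532),
        ("Walking", 0.991938, 0.96951, 0.980596, 0.98332, 2919),
    ],
    columns=["class", "precision", "recall", "f1", "accuracy", "prevalence"],
).set_index("class")

#: Published macro-average row (unweighted means of the columns above).
REFERENCE_MACRO = pd.Series(
    {"precision": 0.832237, "recall": 0.744138, "f1": 0.755321,
     "accuracy": 0.860343}
)

#: Published daily behaviour budgets of the wild deployment
#: (minutes/day and percent-of-day, mean +/- SD across 9 koalas).
REFERENCE_BUDGETS = pd.DataFrame(
    [
        ("Motionless in Tree", 385.2, 194.3, 26.8, 13.5, "07:00-08:00"),
        ("General Movement in Tree", 827.3, 204.7, 57.5, 14.2, "13:00-14:00"),
        ("Feeding & Grooming in Tree", 224.2, 39.2, 15.6, 2.7, "18:00-19:00"),
        ("Walking", 3.0, 1.4, 0.2, 0.1, "02:00-03:00"),
    ],
    columns=["category", "minutes_mean", "minutes_sd", "percent_mean",
             "percent_sd", "peak"],
).set_index("category")

#: Published ground-visit statistics: visits/day and walking minutes/visit.
REFERENCE_VISITS = {"visits_per_day": 2.95, "visits_per_day_sd": 2.31,
                    "minutes_per_visit": 1.59, "minutes_per_visit_sd": 1.95}


def macro_from_classes(table: pd.DataFrame) -> pd.Series:
    """Unweighted macro means of the per-class metric columns."""
    return table[["precision", "recall", "f1", "accuracy"]].mean()


def f1_from_precision_recall(p, r):
    p, r = np.asarray(p, float), np.asarray(r, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(p + r > 0, 2 * p * r / np.where(p + r > 0, p + r, 1), 0.0)


def percent_from_minutes(minutes) -> np.ndarray:
    """Percent of a 1440-min day, rounded half-up to one decimal.

    Uses decimal arithmetic so printed 1-decimal minute values convert
    exactly (e.g. 385.2 min -> 26.75% -> 26.8%), free of binary round-off.
    """
    from decimal import ROUND_HALF_UP, Decimal

    vals = np.atleast_1d(np.asarray(minutes))
    out = [
        float(
            (Decimal(str(v)) * 100 / Decimal(1440)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for v in vals
    ]
    return np.array(out)


def validate_report(metrics: pd.DataFrame | None = None,
                    budgets: pd.DataFrame | None = None,
                    decimals: int = 6) -> pd.DataFrame:
    """Checklist of internal arithmetic for a report bundle.

    ``metrics`` needs per-class rows plus a ``Macro-average`` row with
    precision/recall/f1/accuracy columns; ``budgets`` needs minutes_mean and
    percent_mean per category. Missing inputs yield skipped checks. Each row
    reports check name, status ('pass'/'fail'/'skip') and detail.
    """
    rows = []

    def add(name, status, detail=""):
        rows.append({"check": name, "status": status, "detail": detail})

    if metrics is not None and "Macro-average" in metrics.index:
        classes = metrics.drop(index="Macro-average")
        macro = metrics.loc["Macro-average"]
        derived = macro_from_classes(classes)
        for col in ("precision", "recall", "f1"):
            ok = abs(round(derived[col], decimals) - round(macro[col], decimals)) \
                 < 10 ** (-decimals) * 1.5
            add(f"macro_{col}_is_unweighted_mean", "pass" if ok else "fail",
                f"derived={derived[col]:.6f} reported={macro[col]:.6f}")
        f1 = f1_from_precision_recall(classes["precision"], classes["recall"])
        ok = np.allclose(np.round(f1, decimals),
                         np.round(classes["f1"].to_numpy(), decimals),
                         atol=10 ** (-decimals) * 1.5)
        add("per_class_f1_is_harmonic_mean", "pass" if ok else "fail")
    else:
        add("macro_metrics", "skip", "no metric table")
        add("per_class_f1_is_harmonic_mean", "skip", "no metric table")

    if budgets is not None and len(budgets):
        derived = percent_from_minutes(budgets["minutes_mean"])
        # compare against the unrounded reported percent: the derived value
        # is rounded to 1 decimal, so agreement means within half an ulp
        reported = budgets["percent_mean"].to_numpy(float)
        ok = np.allclose(derived, reported, atol=0.0501)
        add("percent_of_day_follows_minutes", "pass" if ok else "fail",
            f"derived={derived.tolist()} reported={reported.tolist()}")
    else:
        add("percent_of_day_follows_minutes", "skip", "no budget table")

    return pd.DataFrame(rows)


def validate_reference_metrics() -> pd.DataFrame:
    """Run the checklist on the published reference tables themselves."""
    metrics = REFERENCE_CLASS_METRICS.copy()
    metrics.loc["Macro-average"] = REFERENCE_MACRO
    return validate_report(metrics, REFERENCE_BUDGETS)
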