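"""Unbiased clock evaluation: LOOCV, LOSOCV and the metric suite.

Two cross-validation schemes estimate out-of-sample clock accuracy.
Leave-one-sample-out (LOOCV) refits the clock on all but one sample and
predicts that sample, so accuracy is estimated for individuals of species
represented in training.  Leave-one-species-out (LOSOCV) removes every
sample of one species, refits, and predicts the removed species using its
own transform parameters only at inversion — this estimates how the clock
performs on a species never seen during training.  The penalty lambda is
re-selected by internal CV inside every outer fold, so the held-out unit
never influences model selection.

Accuracy metrics follow the conventions of the epigenetic-clock
literature: the age correlation r is the Pearson correlation between DNAm
age and chronological age, and MAE is the *median* absolute error in
years (robust to the occasional gross miss, unlike the mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import fit_clock, predict_age
from .io import Cohort

__all__ = ["Metrics", "CVResult", "compute_metrics", "loocv", "losocv"]


@dataclass
class Metrics:
    overall_r: float
    overall_mae: float
    per_group: pd.DataFrame  # columns: group, n, r, mae
    median_r: float
    median_mae: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN when undefined (n < 2 or a zero-variance vector)."""
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_metrics(true_ages, predicted_ages, groups=None) -> Metrics:
    """Age correlation r and median absolute error, overall and per group.

    ``median_r`` / ``median_mae`` are medians of the per-group values;
    groups whose r is undefined (fewer than 2 members, or zero variance)
    are excluded from the median r with a warning.
    """
    t = np.asarray(true_ages, dtype=float)
    p = np.asarray(predicted_ages, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and predicted age vectors differ in length")
    if len(t) < 2:
        raise ValueError("need at least 2 samples to compute metrics")
    overall_r = _pearson(t, p)
    overall_mae = float(np.median(np.abs(p - t)))
    if groups is None:
        return Metrics(overall_r, overall_mae, pd.DataFrame(), overall_r, overall_mae)

    rows = []
    for g in pd.unique(np.asarray(groups, dtype=object)):
        mask = np.asarray(groups, dtype=object) == g
        r = _pearson(t[mask], p[mask])
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "r": r,
                "mae": float(np.median(np.abs(p[mask] - t[mask]))),
            }
        )
    per_group = pd.DataFrame(rows)
    defined = per_group["r"].notna()
    if (~defined).any():
        warnings.warn(
            "group(s) with undefined age correlation excluded from the "
            f"median: {per_group.loc[~defined, 'group'].tolist()}",
            stacklevel=2,
        )
    median_r = float(per_group.loc[defined, "r"].median()) if defined.any() else float("nan")
    median_mae = float(per_group["mae"].median())
    return Metrics(overall_r, overall_mae, per_group, median_r, median_mae)


@dataclass
class CVResult:
    scheme: str
    stratum: str
    predictions: pd.DataFrame  # sample_id, species, tissue, true_age, predicted_age, heldout_unit
    metrics: Metrics

    def write(self, predictions_path, metrics_path) -> None:
        self.predictions.to_csv(predictions_path, index=False)
        per_group = self.metrics.per_group.copy()
        per_group.to_csv(metrics_path, index=False)


def _aged_stratum(cohort: Cohort, stratum: str) -> Cohort:
    sub = cohort.stratum(stratum)
    aged = sub.sheet["age_years"].notna()
    return sub.subset(sub.sheet.loc[aged, "sample_id"])


def _assemble(scheme, stratum, rows, sheet) -> CVResult:
    pred = pd.DataFrame(rows)
    metrics = compute_metrics(
        pred["true_age"], pred["predicted_age"], groups=pred["species"]
    )
    return CVResult(scheme=scheme, stratum=stratum, predictions=pred, metrics=metrics)


def loocv(
    cohort: Cohort,
    stratum: str = "blood+skin",
    n_folds: int = 10,
    lambda_grid=None,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Leave-one-sample-out cross-validation of the clock on one stratum."""
    sub = _aged_stratum(cohort, stratum)
    if sub.n_samples < 3:
        raise ValueError("LOOCV needs at least 3 aged samples in the stratum")
    rows = []
    for sid in sub.beta.columns:
        train_ids = [s for s in sub.beta.columns if s != sid]
        train = sub.subset(train_ids)
        try:
            model = fit_clock(
                train, stratum, n_folds=n_folds, lambda_grid=lambda_grid,
                seed=seed, **fit_kwargs,
            )
        except ValueError as exc:
            raise ValueError(f"LOOCV fit failed holding out {sid!r}: {exc}") from exc
        pred = predict_age(model, sub.beta[[sid]], sub.sheet, sub.params)
        row = sub.sheet.set_index("sample_id").loc[sid]
        rows.append(
            {
                "sample_id": sid,
                "species": row["species"],
                "tissue": row["tissue"],
                "true_age": float(row["age_years"]),
                "predicted_age": float(pred.iloc[0]),
                "heldout_unit": sid,
            }
        )
    return _assemble("LOOCV", stratum, rows, sub.sheet)


def losocv(
    cohort: Cohort,
    stratum: str = "blood+skin",
    n_folds: int = 10,
    lambda_grid=None,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Leave-one-species-out cross-validation of the clock on one stratum.

    For every held-out species the clock is trained on all other species;
    predictions for the held-out species use its own transform parameters
    only when inverting the linear predictor back to years.
    """
    sub = _aged_stratum(cohort, stratum)
    species_list = sorted(sub.sheet["species"].unique())
    if len(species_list) < 2:
        raise ValueError("LOSOCV needs at least 2 species in the stratum")
    rows = []
    for sp in species_list:
        train_ids = sub.sheet.loc[sub.sheet["species"] != sp, "sample_id"]
        test_ids = sub.sheet.loc[sub.sheet["species"] == sp, "sample_id"]
        train = sub.subset(train_ids)
        model = fit_clock(
            train, stratum, n_folds=n_folds, lambda_grid=lambda_grid,
            seed=seed, **fit_kwargs,
        )
        preds = predict_age(model, sub.beta[list(test_ids)], sub.sheet, sub.params)
        meta = sub.sheet.set_index("sample_id")
        for sid in test_ids:
            rows.append(
                {
                    "sample_id": sid,
                    "species": sp,
                    "tissue": meta.at[sid, "tissue"],
                    "true_age": float(meta.at[sid, "age_years"]),
                    "predicted_age": float(preds[sid]),
                    "heldout_unit": sp,
                }
            )
    return _assemble("LOSOCV", stratum, rows, sub.sheet)
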