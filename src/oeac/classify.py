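"""Random-forest prediction of sex, tissue and species from methylation.

Categorical traits are predicted with a bootstrap ensemble of Gini
decision trees (sqrt(p) candidate features per split, unlimited depth),
and accuracy is summarized by the out-of-bag (OOB) error: each sample is
voted on only by trees whose bootstrap did not contain it.  Species is a
prediction target only, never a feature.  The module also provides the
sex-dimorphic CpG scan — a per-probe Welch t-test between female and male
beta values that surfaces X/Y-linked probes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["TraitClassifier", "fit_forest", "predict_labels", "sex_cpg_scan"]


class TraitClassifier(ClassifierMixin, BaseEstimator):
    """Random forest on beta values with an out-of-bag error estimate.

    Parameters
    ----------
    n_trees : int, default 500
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray of sorted class labels (the tie-break vocabulary).
    oob_error_ : float
        Fraction of OOB-covered samples whose majority OOB vote
        mismatches the true label.
    oob_excluded_ : list of sample ids never out-of-bag (excluded from
        the error denominator, with a warning).
    probe_ids_ : pandas.Index of training probes.
    impute_means_ : per-probe training means used to fill missing betas.
    forest_ : the underlying fitted :class:`RandomForestClassifier`.
    """

    def __init__(self, n_trees: int = 500, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit a classifier")
        if (counts < 2).any():
            small = classes[counts < 2].tolist()
            warnings.warn(f"class(es) with a single sample: {small}", stacklevel=2)
        self.probe_ids_ = X.columns
        vals = X.to_numpy(dtype=float)
        self.impute_means_ = pd.Series(
            np.nan_to_num(np.nanmean(vals, axis=0), nan=0.0), index=self.probe_ids_
        )
        vals = np.where(np.isnan(vals), self.impute_means_.to_numpy()[None, :], vals)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            criterion="gini",
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="Some inputs do not have OOB scores"
            )
            self.forest_.fit(vals, y)
        self.classes_ = self.forest_.classes_
        oob = self.forest_.oob_decision_function_
        covered = ~(np.isnan(oob).any(axis=1) | (oob.sum(axis=1) == 0))
        self.oob_excluded_ = [s for s, c in zip(X.index, covered) if not c]
        if self.oob_excluded_:
            warnings.warn(
                f"sample(s) never out-of-bag excluded from OOB error: "
                f"{self.oob_excluded_[:10]}",
                stacklevel=2,
            )
        votes = self.classes_[np.argmax(oob[covered], axis=1)]
        self.oob_error_ = float(np.mean(votes != y[covered]))
        self.n_features_in_ = X.shape[1]
        return self

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = self.probe_ids_.difference(X.columns)
        if len(missing):
            raise ValueError(f"probes absent from input: {list(missing[:10])}")
        vals = X.reindex(columns=self.probe_ids_).to_numpy(dtype=float)
        return np.where(np.isnan(vals), self.impute_means_.to_numpy()[None, :], vals)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Majority vote across trees; ties go to the first class in
        sorted vocabulary order."""
        check_is_fitted(self, "forest_")
        proba = self.forest_.predict_proba(self._matrix(X))
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._matrix(X))


def fit_forest(
    beta: pd.DataFrame, labels, n_trees: int = 500, seed: int = 0
) -> TraitClassifier:
    """Fit a trait forest on a probes x samples beta matrix."""
    est = TraitClassifier(n_trees=n_trees, random_state=seed)
    labels = pd.Series(np.asarray(labels, dtype=object), index=beta.columns)
    return est.fit(beta.T, labels.to_numpy())


def predict_labels(model: TraitClassifier, beta: pd.DataFrame):
    """Predicted class and per-class vote fractions for each sample column."""
    X = beta.T
    pred = pd.Series(model.predict(X), index=beta.columns, name="predicted")
    votes = pd.DataFrame(model.predict_proba(X), index=beta.columns, columns=model.classes_)
    return pred, votes


def sex_cpg_scan(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe Welch t-test of beta values between females and males.

    Returns a DataFrame ranked by ascending p (ties by probe id) with
    columns ``mean_F, mean_M, t, p, direction, rank``; ``direction`` is
    the sign of mean_M - mean_F.  Probes with undefined statistics
    (constant in both sexes) get NaN p and are placed last, unranked.
    """
    meta = sheet.set_index("sample_id").loc[list(beta.columns)]
    f_ids = meta.index[meta["sex"] == "F"]
    m_ids = meta.index[meta["sex"] == "M"]
    if len(f_ids) < 2 or len(m_ids) < 2:
        raise ValueError(
            f"need >= 2 samples of each sex; got F={len(f_ids)}, M={len(m_ids)}"
        )
    xf = beta[list(f_ids)].to_numpy(dtype=float)
    xm = beta[list(m_ids)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(xf, xm, axis=1, equal_var=False, nan_policy="omit")
    mean_f = np.nanmean(xf, axis=1)
    mean_m = np.nanmean(xm, axis=1)
    out = pd.DataFrame(
        {
            "mean_F": mean_f,
            "mean_M": mean_m,
            "t": res.statistic,
            "p": res.pvalue,
            "direction": np.sign(mean_m - mean_f).astype(int),
        },
        index=beta.index,
    )
    out.loc[~np.isfinite(out["t"]), ["t", "p"]] = np.nan
    defined = out["p"].notna()
    ranked = out[defined]
    order = np.lexsort((ranked.index.to_numpy(), ranked["p"].to_numpy()))
    out = pd.concat([ranked.iloc[order], out[~defined]])
    out["rank"] = pd.array(np.arange(1, len(out) + 1), dtype="Int64")
    out.loc[out["p"].isna(), "rank"] = pd.NA
    out.index.name = "probe_id"
    return out
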