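"""Sparse penalized-regression aging clocks.

The clock is an L1-penalized (LASSO) linear model on CpG beta values whose
response is chronological age transformed per sample through that sample's
species-specific log-linear transform (see :mod:`oeac.transform`).  The
penalty weight lambda is chosen by internal k-fold cross-validation
(default 10 folds, stratified by species) as the minimizer of mean CV
squared error over a descending geometric lambda grid.  Predicted
transformed ages are mapped back to years with the species' inverse
transform and clipped below at zero.

:class:`EpigeneticClock` is a scikit-learn style estimator operating on a
samples x probes matrix; :func:`fit_clock` / :func:`predict_age` are the
cohort-level wrappers, and :func:`save_clock` / :func:`load_clock` persist
the sparse model losslessly as a commented CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path
from sklearn.utils.validation import check_is_fitted

from .io import Cohort
from .transform import AgeTransform

__all__ = [
    "EpigeneticClock",
    "ClockModel",
    "fit_clock",
    "predict_age",
    "save_clock",
    "load_clock",
    "make_lambda_grid",
    "species_fold_assignment",
]


def make_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 40, min_ratio: float = 3e-2
) -> np.ndarray:
    """Descending geometric lambda grid from the smallest all-zero lambda.

    The largest grid value is max_j |x_j . (y - ybar)| / n computed on
    unit-variance standardized predictors, below which at least one
    coefficient becomes active.
    """
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    yc = y - y.mean()
    lam_max = np.max(np.abs((xc / sd).T @ yc)) / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def species_fold_assignment(
    sample_ids, species, n_folds: int, seed: int
) -> pd.Series:
    """Seeded fold labels (0..n_folds-1) stratified by species.

    Assignment depends only on the set of (sample_id, species) pairs and
    the seed, never on input order: samples are processed species by
    species in sorted order, shuffled within species, and dealt
    round-robin with a counter rolling across species so fold sizes stay
    balanced even when a species has fewer samples than folds.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"sample_id": list(sample_ids), "species": list(species)})
    df = df.sort_values(["species", "sample_id"], kind="stable")
    folds = {}
    counter = int(rng.integers(n_folds))
    for _, group in df.groupby("species", sort=True):
        ids = group["sample_id"].to_numpy()
        rng.shuffle(ids)
        for sid in ids:
            folds[sid] = counter % n_folds
            counter += 1
    return pd.Series([folds[s] for s in sample_ids], index=list(sample_ids))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _fit_lasso_at(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-3,
                  max_iter: int = 500):
    """Fit a single standardized lasso; returns intercept and original-scale coefs."""
    Xs, mean, sd = _standardize(X)
    ybar = y.mean()
    if lam == math.inf:
        return ybar, np.zeros(X.shape[1])
    _, coefs, _ = lasso_path(
        np.asfortranarray(Xs), y - ybar, alphas=[lam], tol=tol, max_iter=max_iter
    )
    beta_std = coefs[:, 0]
    beta = beta_std / sd
    intercept = ybar - float(mean @ beta)
    return intercept, beta


class EpigeneticClock(RegressorMixin, BaseEstimator):
    """LASSO aging clock on methylation beta values.

    Parameters
    ----------
    species_params : pandas.DataFrame
        Table with columns ``species, asm_years, gestation_years`` giving
        each species' age at sexual maturity and gestation time (years),
        which parameterize the log-linear age transform.
    n_folds : int, default 10
        Folds for the internal cross-validation that selects lambda.
    lambda_grid : array-like or None
        Explicit penalty grid; if None a descending geometric grid of
        ``n_lambdas`` values is derived from the training data.
    n_lambdas : int, default 40
    lambda_min_ratio : float, default 0.03
        Ratio of the smallest to the largest grid lambda.
    tol, max_iter :
        Coordinate-descent convergence controls passed to the solver.
    random_state : int, default 0
        Seed for the species-stratified fold assignment.

    Attributes
    ----------
    probe_ids_ : pandas.Index of training probes (model column order).
    coef_ : ndarray of per-probe coefficients on the original beta scale.
    intercept_ : float
    lambda_ : float, the selected penalty.
    cv_mse_ : ndarray, mean CV squared error per grid lambda.
    lambda_grid_ : ndarray, the descending grid actually used.
    impute_means_ : pandas.Series, training-set probe means used to fill
        missing betas at fit and predict time.
    n_features_in_ : int
    """

    def __init__(
        self,
        species_params: pd.DataFrame | None = None,
        n_folds: int = 10,
        lambda_grid=None,
        n_lambdas: int = 40,
        lambda_min_ratio: float = 3e-2,
        tol: float = 1e-3,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.species_params = species_params
        self.n_folds = n_folds
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers -------------------------------------------------------
    def _transforms(self) -> dict[str, AgeTransform]:
        if self.species_params is None:
            raise ValueError("species_params must be provided")
        return {
            row["species"]: AgeTransform(
                float(row["asm_years"]), float(row["gestation_years"])
            )
            for _, row in self.species_params.iterrows()
        }

    def _transform_ages(self, ages, species) -> np.ndarray:
        tr = self._transforms()
        missing = sorted(set(species) - set(tr))
        if missing:
            raise ValueError(f"species without transform parameters: {missing}")
        return np.array(
            [tr[sp](a) for a, sp in zip(np.asarray(ages, float), species)]
        )

    # -- sklearn API ---------------------------------------------------
    def fit(self, X: pd.DataFrame, y, species=None):
        """Fit the clock.

        ``X`` is a samples x probes DataFrame indexed by sample id; ``y``
        holds chronological ages in years; ``species`` gives each
        sample's species (used both for the response transform and to
        stratify CV folds).
        """
        if species is None:
            raise ValueError("species labels are required to transform ages")
        X = pd.DataFrame(X)
        n = X.shape[0]
        if n < self.n_folds:
            raise ValueError(f"{n} samples < {self.n_folds} CV folds")
        species = np.asarray(species, dtype=object)
        y_t = self._transform_ages(y, species)
        if np.ptp(y_t) == 0:
            raise ValueError("constant transformed response; cannot fit clock")

        # canonical sample order: results independent of input row order
        order = np.argsort(X.index.to_numpy())
        X = X.iloc[order]
        y_t = y_t[order]
        species = species[order]

        self.probe_ids_ = X.columns
        self.n_features_in_ = X.shape[1]
        vals = X.to_numpy(dtype=float)
        col_mean = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        self.impute_means_ = pd.Series(col_mean, index=self.probe_ids_)
        nan_mask = np.isnan(vals)
        if nan_mask.any():
            vals = np.where(nan_mask, col_mean[None, :], vals)

        if self.lambda_grid is not None:
            grid = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
        else:
            grid = make_lambda_grid(vals, y_t, self.n_lambdas, self.lambda_min_ratio)
        finite = grid[np.isfinite(grid)]

        folds = species_fold_assignment(
            X.index, species, self.n_folds, self.random_state
        ).to_numpy()
        self.fold_assignment_ = pd.Series(folds, index=X.index)

        if len(finite) == 0:
            # fully penalized limit: intercept-only model
            self.cv_mse_ = np.full(len(grid), np.nan)
            self.lambda_grid_ = grid
            self.lambda_ = float(grid[0])
            self.intercept_ = float(y_t.mean())
            self.coef_ = np.zeros(vals.shape[1])
        else:
            sse = np.zeros(len(finite))
            for f in range(self.n_folds):
                test = folds == f
                if not test.any():
                    continue
                train = ~test
                Xs, mean, sd = _standardize(vals[train])
                ybar = y_t[train].mean()
                _, coefs, _ = lasso_path(
                    np.asfortranarray(Xs),
                    y_t[train] - ybar,
                    alphas=finite,
                    tol=self.tol,
                    max_iter=self.max_iter,
                )
                beta = coefs / sd[:, None]
                icpt = ybar - mean @ beta
                pred = vals[test] @ beta + icpt[None, :]
                sse += ((pred - y_t[test][:, None]) ** 2).sum(axis=0)
            cv_mse = sse / n
            # ties resolved toward the larger (sparser) lambda
            best = int(np.argmin(cv_mse))
            self.cv_mse_ = cv_mse
            self.lambda_grid_ = finite
            self.lambda_ = float(finite[best])
            self.intercept_, self.coef_ = _fit_lasso_at(
                vals, y_t, self.lambda_, tol=self.tol, max_iter=self.max_iter
            )
        return self

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Transformed-age prediction (intercept + beta . x) per sample."""
        check_is_fitted(self, "coef_")
        X = pd.DataFrame(X)
        missing = self.probe_ids_.difference(X.columns)
        used = self.probe_ids_[self.coef_ != 0]
        missing_used = [p for p in used if p in missing]
        if missing_used:
            raise ValueError(f"model probes absent from input: {missing_used[:10]}")
        X = X.reindex(columns=self.probe_ids_)
        # contiguous copy: keeps the dot product bit-identical under
        # probe-order permutations of the input
        vals = np.ascontiguousarray(X.to_numpy(dtype=float))
        nan_mask = np.isnan(vals)
        if nan_mask.any():
            vals = np.where(nan_mask, self.impute_means_.to_numpy()[None, :], vals)
        return vals @ self.coef_ + self.intercept_

    def predict(self, X: pd.DataFrame, species=None) -> np.ndarray:
        """Predict DNAm age in years (non-negative) for each sample."""
        if species is None:
            raise ValueError("species labels are required to invert the age transform")
        lp = self.linear_predictor(X)
        tr = self._transforms()
        missing = sorted(set(species) - set(tr))
        if missing:
            raise ValueError(f"species without transform parameters: {missing}")
        return np.array([tr[sp].inverse(v) for v, sp in zip(lp, species)])

    @property
    def weights_(self) -> pd.Series:
        """Nonzero coefficients as a probe-indexed Series."""
        check_is_fitted(self, "coef_")
        nz = self.coef_ != 0
        return pd.Series(self.coef_[nz], index=self.probe_ids_[nz], name="coefficient")


@dataclass
class ClockModel:
    """Portable sparse clock: stratum, intercept and nonzero probe weights."""

    stratum: str
    intercept: float
    weights: pd.Series  # probe_id -> coefficient, nonzero only
    lambda_: float
    seed: int
    impute_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def predict(
        self, beta: pd.DataFrame, sheet: pd.DataFrame, params: pd.DataFrame
    ) -> pd.Series:
        return predict_age(self, beta, sheet, params)


def fit_clock(
    cohort: Cohort,
    stratum: str = "blood+skin",
    n_folds: int = 10,
    lambda_grid=None,
    seed: int = 0,
    **kwargs,
) -> ClockModel:
    """Train a clock on one tissue stratum of a cohort.

    Only samples with a non-missing age are used.  Returns the portable
    sparse :class:`ClockModel`; use :class:`EpigeneticClock` directly for
    the full estimator (CV curve, dense coefficients, fold assignment).
    """
    sub = cohort.stratum(stratum)
    aged = sub.sheet["age_years"].notna()
    sub = sub.subset(sub.sheet.loc[aged, "sample_id"])
    est = EpigeneticClock(
        species_params=cohort.params,
        n_folds=n_folds,
        lambda_grid=lambda_grid,
        random_state=seed,
        **kwargs,
    )
    est.fit(
        sub.beta.T,
        sub.sheet["age_years"].to_numpy(),
        species=sub.sheet["species"].to_numpy(),
    )
    w = est.weights_
    return ClockModel(
        stratum=stratum,
        intercept=float(est.intercept_),
        weights=w,
        lambda_=float(est.lambda_),
        seed=seed,
        impute_means=est.impute_means_.loc[w.index],
    )


def predict_age(
    model: ClockModel,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    params: pd.DataFrame,
) -> pd.Series:
    """DNAm age in years for every sample column of ``beta``.

    The linear predictor uses the model's sparse weights (missing betas
    filled with the stored training means) and is inverted through each
    sample's own species transform.
    """
    sheet = sheet.set_index("sample_id")
    missing_samples = [s for s in beta.columns if s not in sheet.index]
    if missing_samples:
        raise ValueError(f"samples missing from sheet: {missing_samples[:10]}")
    absent = model.weights.index.difference(beta.index)
    if len(absent):
        raise ValueError(f"model probes absent from beta matrix: {list(absent[:10])}")
    sub = beta.loc[model.weights.index].to_numpy(dtype=float)
    nan_mask = np.isnan(sub)
    if nan_mask.any():
        fill = model.impute_means.reindex(model.weights.index).to_numpy()
        sub = np.where(nan_mask, fill[:, None], sub)
    lp = model.weights.to_numpy() @ sub + model.intercept

    transforms: dict[str, AgeTransform] = {}
    ages = np.empty(len(beta.columns))
    for i, sid in enumerate(beta.columns):
        sp = sheet.at[sid, "species"]
        if sp not in transforms:
            row = params.loc[params["species"] == sp]
            if row.empty:
                raise ValueError(f"no transform parameters for species {sp!r}")
            transforms[sp] = AgeTransform(
                float(row["asm_years"].iloc[0]), float(row["gestation_years"].iloc[0])
            )
        ages[i] = transforms[sp].inverse(lp[i])
    return pd.Series(ages, index=beta.columns, name="dnam_age")


def save_clock(model: ClockModel, path) -> None:
    """Write a clock model CSV; floats use shortest-exact representation."""
    with open(path, "w") as fh:
        fh.write(f"#stratum={model.stratum}\n")
        fh.write(f"#intercept={float(model.intercept)!r}\n")
        fh.write(f"#lambda={float(model.lambda_)!r}\n")
        fh.write(f"#seed={model.seed}\n")
        fh.write("probe_id,coefficient,impute_mean\n")
        for pid, coef in model.weights.items():
            mean = model.impute_means.get(pid, float("nan"))
            fh.write(f"{pid},{float(coef)!r},{float(mean)!r}\n")


def load_clock(path) -> ClockModel:
    """Read a clock model CSV written by :func:`save_clock` (bit-exact)."""
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key] = val
            elif line and not line.startswith("probe_id,"):
                pid, coef, mean = line.split(",")
                rows.append((pid, float(coef), float(mean)))
    weights = pd.Series(
        {pid: c for pid, c, _ in rows}, dtype=float, name="coefficient"
    )
    means = pd.Series({pid: m for pid, _, m in rows}, dtype=float)
    return ClockModel(
        stratum=header["stratum"],
        intercept=float(header["intercept"]),
        weights=weights,
        lambda_=float(header["lambda"]),
        seed=int(header["seed"]),
        impute_means=means,
    )
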