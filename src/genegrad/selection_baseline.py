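"""Methylation-aware gene-level mutation-burden baselines for selection.

Per-gene mutation counts across a cohort are modelled with a
negative-binomial GLM: log expected burden = log(gene length) + trinucleotide
composition + numeric epigenomic covariates, optionally plus the methylation
gene-group label (c1..c5). Known cancer genes are excluded from fitting; the
excess burden 100*(y - yhat)/yhat of the held-out genes is an effect-size
proxy for positive selection. Model variants (base, +methylation, +shuffled
labels) are compared by cross-validated RMSE and by likelihood-ratio tests of
the group term.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import GLMFit, fit_count_glm

VARIANTS = ("base", "methylation", "shuffled")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def _feature_columns(features: pd.DataFrame) -> tuple[list[str], list[str]]:
    tri = sorted(c for c in features.columns if c.startswith("tri_"))
    cov = sorted(c for c in features.columns if c.startswith("cov_"))
    return tri, cov


def _design(
    features: pd.DataFrame,
    group_levels: Sequence[str] | None,
    group_col: str = "group",
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, trinucleotide fractions (one dropped as the
    reference to break the sum-to-one collinearity), numeric covariates and,
    when ``group_levels`` is given, treatment-coded group dummies."""
    tri, cov = _feature_columns(features)
    cols = [np.ones(len(features))]
    names = ["intercept"]
    for c in tri[1:]:  # drop the first fraction: reference composition
        cols.append(features[c].to_numpy(dtype=float))
        names.append(c)
    for c in cov:
        cols.append(features[c].to_numpy(dtype=float))
        names.append(c)
    if group_levels is not None:
        for level in group_levels[1:]:
            cols.append((features[group_col] == level).to_numpy(dtype=float))
            names.append(f"group_{level}")
    return np.column_stack(cols), names


@dataclasses.dataclass
class BurdenModel:
    """A fitted gene-burden GLM plus what is needed to predict new genes."""

    fit: GLMFit
    names: list[str]
    variant: str
    group_levels: list[str] | None
    group_col: str

    @property
    def llf(self) -> float:
        return self.fit.llf

    @property
    def deviance_proxy(self) -> float:
        # -2 llf at the common dispersion; nested models compare directly
        return -2.0 * self.fit.llf

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X, _ = _design(features, self.group_levels, self.group_col)
        offset = np.log(features["length"].to_numpy(dtype=float))
        return self.fit.predict(X, offset)


def fit_burden_model(
    features: pd.DataFrame,
    variant: str = "base",
    shuffled_col: str = "group_shuffled",
    include_cancer_genes: bool = False,
    model: str = "nb",
) -> BurdenModel:
    """Fit one burden-model variant on the non-cancer genes.

    ``variant`` is "base" (length offset + trinucleotide composition +
    covariates), "methylation" (+ group label) or "shuffled" (+ the
    pre-shuffled label column). Cancer genes are excluded from fitting unless
    ``include_cancer_genes``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    train = features if include_cancer_genes else features[~features["is_cancer_gene"]]
    group_col = {"base": None, "methylation": "group", "shuffled": shuffled_col}[
        variant
    ]
    levels = None
    if group_col is not None:
        levels = sorted(features[group_col].unique())
    X, names = _design(train, levels, group_col or "group")
    y = train["y"].to_numpy(dtype=float)
    offset = np.log(train["length"].to_numpy(dtype=float))
    fit = fit_count_glm(y, X, offset, model=model)
    return BurdenModel(
        fit=fit,
        names=names,
        variant=variant,
        group_levels=levels,
        group_col=group_col or "group",
    )


def group_term_lrt(
    features: pd.DataFrame,
    variant: str = "methylation",
    shuffled_col: str = "group_shuffled",
    model: str = "nb",
) -> tuple[float, float]:
    """Likelihood-ratio test of the group term against the nested base model.

    Returns (statistic, p-value); both fits use the same observations.
    """
    base = fit_burden_model(features, "base", model=model)
    full = fit_burden_model(features, variant, shuffled_col=shuffled_col, model=model)
    df = len(full.names) - len(base.names)
    stat = max(0.0, 2.0 * (full.llf - base.llf))
    return stat, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Label shuffling
# ---------------------------------------------------------------------------


def shuffle_labels(labels: pd.Series, seed: int) -> pd.Series:
    """Uniform random permutation of the label multiset (class counts kept)."""
    rng = np.random.default_rng(seed)
    values = labels.to_numpy().copy()
    rng.shuffle(values)
    return pd.Series(values, index=labels.index, name=labels.name)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BurdenModelReport:
    """Cross-validated comparison of the burden-model variants."""

    rmse: pd.DataFrame  # one row per (run, variant)
    lrt: pd.DataFrame  # one row per (run, fold, variant in {methylation, shuffled})
    predictions: pd.DataFrame  # per-gene mean out-of-fold prediction per variant
    excess: pd.DataFrame  # per-gene excess burden % per variant

    def mean_rmse(self) -> pd.Series:
        return self.rmse.groupby("variant")["rmse"].mean()


def crossvalidate_burden(
    features: pd.DataFrame,
    runs: int = 15,
    folds: int = 5,
    seed: int = 0,
    model: str = "nb",
) -> BurdenModelReport:
    """Repeated k-fold cross-validation of the three burden-model variants.

    Folds are stratified over non-cancer genes only and shared across
    variants within a run; cancer genes are never used for fitting and are
    scored by every fold's model. RMSE is computed on raw counts per fold and
    averaged within a run. The shuffled variant re-shuffles labels once per
    run. The group-term LRT is evaluated on each fold's training fit, giving
    runs x folds p-values per grouped variant.
    """
    rng = np.random.default_rng(seed)
    non_cancer = features.index[~features["is_cancer_gene"]].to_numpy()
    rmse_rows, lrt_rows = [], []
    pred_sums = {v: np.zeros(len(features)) for v in VARIANTS}
    pred_counts = {v: np.zeros(len(features)) for v in VARIANTS}

    for run in range(runs):
        fold_of = dict(
            zip(non_cancer, rng.permutation(np.arange(len(non_cancer)) % folds))
        )
        work = features.copy()
        work["group_shuffled"] = shuffle_labels(
            work["group"], seed=int(rng.integers(2**31))
        )
        fold_rmse = {v: [] for v in VARIANTS}
        for fold in range(folds):
            test_idx = np.array([i for i in non_cancer if fold_of[i] == fold])
            train_idx = np.array([i for i in non_cancer if fold_of[i] != fold])
            train, test = work.loc[train_idx], work.loc[test_idx]
            fold_fits: dict[str, BurdenModel] = {}
            for variant in VARIANTS:
                fitted = fit_burden_model(train, variant, model=model,
                                          include_cancer_genes=True)
                fold_fits[variant] = fitted
                # a level absent from training scores as the base prediction
                test_eval = test.copy()
                if fitted.group_levels is not None:
                    known = set(fitted.group_levels)
                    col = fitted.group_col
                    unknown = ~test_eval[col].isin(known)
                    if unknown.any():
                        test_eval.loc[unknown, col] = fitted.group_levels[0]
                yhat = fitted.predict(test_eval)
                resid = test_eval["y"].to_numpy(dtype=float) - yhat
                fold_rmse[variant].append(float(np.sqrt(np.mean(resid**2))))
                pos = features.index.get_indexer(test_idx)
                pred_sums[variant][pos] += yhat
                pred_counts[variant][pos] += 1
                # cancer genes: scored by every fold's model
                cancer = work.loc[features["is_cancer_gene"]]
                if len(cancer):
                    cpos = features.index.get_indexer(cancer.index)
                    pred_sums[variant][cpos] += fitted.predict(cancer)
                    pred_counts[variant][cpos] += 1
            # group-term LRT of each grouped variant against the base fit,
            # on this fold's training data (runs x folds p-values)
            for variant in ("methylation", "shuffled"):
                df = len(fold_fits[variant].names) - len(fold_fits["base"].names)
                stat = max(0.0, 2.0 * (fold_fits[variant].llf - fold_fits["base"].llf))
                lrt_rows.append(
                    {"run": run, "fold": fold, "variant": variant,
                     "stat": stat, "pvalue": float(stats.chi2.sf(stat, df))}
                )
        for variant in VARIANTS:
            rmse_rows.append(
                {
                    "run": run,
                    "variant": variant,
                    "rmse": float(np.mean(fold_rmse[variant])),
                }
            )

    preds = pd.DataFrame(index=features.index)
    preds["gene_id"] = features["gene_id"]
    preds["y"] = features["y"]
    preds["is_cancer_gene"] = features["is_cancer_gene"]
    for v in VARIANTS:
        with np.errstate(invalid="ignore"):
            preds[f"pred_{v}"] = pred_sums[v] / np.maximum(pred_counts[v], 1)
    excess = preds[["gene_id", "is_cancer_gene"]].copy()
    for v in VARIANTS:
        excess[f"excess_{v}"] = excess_burden(
            preds["y"].to_numpy(dtype=float), preds[f"pred_{v}"].to_numpy()
        )
    return BurdenModelReport(
        rmse=pd.DataFrame(rmse_rows),
        lrt=pd.DataFrame(lrt_rows),
        predictions=preds,
        excess=excess,
    )


def excess_burden(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Per-gene excess mutation burden, 100*(y - yhat)/yhat."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if (predicted <= 0).any():
        raise ValueError("predictions must be positive")
    return 100.0 * (observed - predicted) / predicted
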