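"""Penalized log-linear model of inter-domain expression fold change.

The response for gene i is the average (over stages S4 and S6) log2 fold
change between two compared floral domains; the features are normalized
TF-binding scores x_ij for the J profiled TFs (0 for unbound genes),
scaled to unit variance and mean-centered.  A Lasso fit

    Y_i = sum_j beta_j x_ij + eps_i

with the penalty chosen by five repeats of ten-fold cross-validation
yields per-TF contributions beta_j to the organ-to-organ expression
contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import RepeatedKFold

from .domains import DomainExpressionTable


@dataclass
class RegressionDataset:
    genes: list[str]
    feature_names: list[str]
    X: np.ndarray  # genes x TFs, unit-variance then mean-centered
    y: np.ndarray
    comparison: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.genes), len(self.feature_names)):
            raise ValueError("X shape does not match genes x features")
        if len(self.y) != len(self.genes):
            raise ValueError("y length does not match genes")


@dataclass
class FittedModel:
    coefficients: pd.Series
    intercept: float
    lambda_: float
    cv_error_mean: float
    cv_error_sd: float
    comparison: str = ""

    @property
    def support(self) -> set[str]:
        return set(self.coefficients.index[self.coefficients != 0])


def build_dataset(
    genes: list[str],
    domain_expr: DomainExpressionTable,
    target_scores: pd.DataFrame,
    domain_pair: tuple[str, str],
    pseudocount: float = 1.0,
) -> RegressionDataset:
    """Assemble Y (inter-domain log2 FC) and X (binding scores) per gene.

    ``target_scores`` is genes x TFs with 0 for unbound; Y_i averages the
    per-stage log2 ratios of pseudocounted domain means.  Features are
    scaled to unit variance then mean-centered; zero-variance columns are
    dropped with a warning.
    """
    dom_a, dom_b = domain_pair
    idx = {g: i for i, g in enumerate(domain_expr.genes)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise KeyError(f"genes missing from translatome: {missing[:5]}")

    y = np.zeros(len(genes))
    for gi, g in enumerate(genes):
        row = idx[g]
        ratios = []
        for s in domain_expr.stages:
            ma = domain_expr.values[row, domain_expr.columns(dom_a, s)].mean()
            mb = domain_expr.values[row, domain_expr.columns(dom_b, s)].mean()
            ratios.append(np.log2((ma + pseudocount) / (mb + pseudocount)))
        y[gi] = np.mean(ratios)

    X = target_scores.reindex(index=genes).fillna(0.0)
    sd = X.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        X = X.loc[:, keep]
        sd = sd[keep]
    Xv = X.values / sd
    Xv = Xv - Xv.mean(axis=0)
    return RegressionDataset(
        genes=list(genes),
        feature_names=list(X.columns),
        X=Xv,
        y=y,
        comparison=f"{dom_a}-vs-{dom_b}",
    )


def fit_lasso(
    dataset: RegressionDataset,
    n_repeats: int = 5,
    n_folds: int = 10,
    seed: int | None = None,
    n_alphas: int = 100,
    rule: str = "1se",
) -> FittedModel:
    """Lasso over a log-spaced penalty path with repeated-CV selection.

    Cross-validation uses ``n_repeats`` repeats of ``n_folds``-fold splits
    (the 5x10 scheme by default).  ``rule`` picks the penalty: ``"1se"``
    (default) takes the largest penalty whose mean CV error is within one
    standard error of the minimum — the standard parsimony rule, which
    recovers sparse supports where the raw CV minimum keeps spurious
    near-zero coefficients; ``"min"`` takes the CV-minimum penalty.  The
    intercept is fitted but unpenalized and is ~0 on centered data.
    Deterministic given the seed.
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"rule must be 'min' or '1se', got {rule!r}")
    n = len(dataset.genes)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} observations")
    if n < 5 * len(dataset.feature_names):
        warnings.warn(
            f"only {n} observations for {len(dataset.feature_names)} features",
            stacklevel=2,
        )
    cv = RepeatedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    model = LassoCV(alphas=n_alphas, cv=cv, max_iter=50_000)
    model.fit(dataset.X, dataset.y)
    # mse_path_: (n_alphas, n_folds*n_repeats), alphas_ descending
    mse_mean = model.mse_path_.mean(axis=1)
    i_min = int(np.argmin(mse_mean))
    if rule == "min":
        i_sel = i_min
    else:
        # glmnet-style SE: fold MSEs are positively correlated across
        # repeats, so only n_folds effectively independent groups
        se_min = model.mse_path_[i_min].std(ddof=1) / np.sqrt(n_folds)
        within = np.nonzero(mse_mean <= mse_mean[i_min] + se_min)[0]
        i_sel = int(within[0])  # largest alpha within one SE
    alpha = float(model.alphas_[i_sel])
    if i_sel != i_min:
        from sklearn.linear_model import Lasso

        refit = Lasso(alpha=alpha, max_iter=50_000).fit(dataset.X, dataset.y)
        coef, intercept = refit.coef_, refit.intercept_
    else:
        coef, intercept = model.coef_, model.intercept_
    return FittedModel(
        coefficients=pd.Series(coef, index=dataset.feature_names),
        intercept=float(intercept),
        lambda_=alpha,
        cv_error_mean=float(model.mse_path_[i_sel].mean()),
        cv_error_sd=float(model.mse_path_[i_sel].std(ddof=1)),
        comparison=dataset.comparison,
    )


def coefficient_heatmap_table(models: list[FittedModel]) -> pd.DataFrame:
    """TF x domain-comparison matrix of Lasso coefficients."""
    if not models:
        raise ValueError("no models supplied")
    names = list(models[0].coefficients.index)
    for m in models[1:]:
        if list(m.coefficients.index) != names:
            raise ValueError("models have inconsistent TF feature sets")
    return pd.DataFrame(
        {m.comparison or f"model_{i}": m.coefficients for i, m in enumerate(models)}
    )
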