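"""Drug-response imputation: per-drug ridge regression on cell-line screens.

A model is trained for every drug that survives the screening-coverage
filter: AUC over cell lines is regressed on genome-wide expression with an
L2 penalty, on gene-standardized predictors and centered response, using
only the lines actually screened for that drug. The penalty defaults to the
minimizer of the closed-form leave-one-out error. Tumor samples are first
harmonized against the training transcriptomes by per-gene rank-to-quantile
mapping (a rank-preserving stand-in for cross-platform integration), then
scored as ``intercept + beta^T x``; lower imputed AUC = predicted more
sensitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nomination import bh_adjust

__all__ = [
    "RidgeModel",
    "filter_drugs",
    "harmonize",
    "fit_ridge",
    "fit_models",
    "impute",
    "impute_panel",
    "gene_response_correlation",
    "spearman_table",
]

logger = logging.getLogger(__name__)

#: drugs trained on fewer lines than this are flagged in model metadata
SMALL_TRAIN_N = 20

_DEFAULT_LAMBDA_GRID = np.logspace(-4.0, 4.0, 25)


def filter_drugs(screen: pd.DataFrame, min_fraction: float = 0.40) -> pd.DataFrame:
    """Drop drugs screened across less than ``min_fraction`` of all lines.

    The removal rule is strict (coverage < threshold is removed), so a drug
    screened in exactly 40% of lines is retained. Cell lines are unchanged.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if screen.shape[0] == 0 or screen.shape[1] == 0:
        raise ValueError("screen is empty")
    coverage = screen.notna().mean(axis=0)
    keep = coverage >= min_fraction
    if not keep.any():
        warnings.warn("coverage filter removed every drug", stacklevel=2)
    logger.info("coverage filter (>=%.0f%%): kept %d of %d drugs",
                100 * min_fraction, int(keep.sum()), screen.shape[1])
    return screen.loc[:, keep]


def harmonize(train: pd.DataFrame,
              test: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map test expression onto the train distribution, gene by gene.

    Both matrices are restricted to the shared genes in train order. For
    each gene, the test samples' values are replaced by the empirical
    quantiles of the *train* distribution at the test values' (mid)rank
    positions, so only the test ranks survive: any per-gene monotone
    platform distortion is removed, and downstream rank statistics are
    unaffected. Train values are returned unchanged.
    """
    shared = train.index.intersection(test.index)
    if len(shared) == 0:
        raise ValueError(
            f"no shared gene IDs between train (e.g. {list(train.index[:3])}) "
            f"and test (e.g. {list(test.index[:3])})")
    shared = train.index[train.index.isin(shared)]   # train order
    train_s = train.loc[shared]
    test_s = test.loc[shared]
    n_test = test_s.shape[1]
    out = np.empty(test_s.shape)
    tvals = train_s.to_numpy()
    xvals = test_s.to_numpy()
    if n_test == 1:
        probs = np.full((len(shared), 1), 0.5)
    else:
        ranks = stats.rankdata(xvals, axis=1)
        probs = (ranks - 1.0) / (n_test - 1.0)
    for i in range(len(shared)):
        out[i] = np.quantile(tvals[i], probs[i], method="linear")
    harmonized = pd.DataFrame(out, index=shared, columns=test_s.columns)
    return train_s.copy(), harmonized


@dataclass
class RidgeModel:
    """Fitted per-drug ridge model on standardized expression."""

    drug: str
    genes: list[str]
    coef: np.ndarray          # weights on the (centered/scaled) predictor scale
    intercept: float          # training mean AUC
    lam: float
    n_train: int
    gene_mean: np.ndarray
    gene_scale: np.ndarray
    small_n: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.genes):
            raise ValueError("coefficient vector length must match gene list")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError("ridge penalty must be finite and positive")


def _loo_lambda(U: np.ndarray, s: np.ndarray, y: np.ndarray,
                grid: np.ndarray) -> float:
    """Penalty minimizing the closed-form ridge leave-one-out error.

    Uses the identity e_loo,i = (y_i - yhat_i) / (1 - h_ii) with the hat
    diagonal h_ii = sum_j U_ij^2 s_j^2 / (s_j^2 + lambda).
    """
    Uty = U.T @ y
    U2 = U**2
    best_lam, best_err = grid[0], np.inf
    for lam in grid:
        shrink = s**2 / (s**2 + lam)
        yhat = U @ (shrink * Uty)
        h = U2 @ shrink
        denom = np.clip(1.0 - h, 1e-10, None)
        err = float(np.mean(((y - yhat) / denom) ** 2))
        if err < best_err:
            best_lam, best_err = lam, err
    return float(best_lam)


def fit_ridge(train_expr: pd.DataFrame, auc: pd.Series, drug: str = "",
              lam_mode: str = "loo", lam: float = 1.0,
              lam_grid: np.ndarray | None = None,
              standardize: bool = True) -> RidgeModel:
    """Fit one drug's ridge model, using only lines with a screened AUC.

    Solves ``beta = (X^T X + lambda I)^{-1} X^T y`` via SVD on
    gene-standardized X (training mean/SD, stored for prediction) and
    centered y; the intercept is the training mean AUC. ``lam_mode`` is
    ``"loo"`` (closed-form leave-one-out minimization over ``lam_grid``) or
    ``"fixed"``. Zero-variance genes are dropped with a logged warning.
    ``standardize=False`` uses the raw predictor matrix (still centering y),
    mainly for closed-form verification.
    """
    auc = auc.reindex(train_expr.columns)
    mask = auc.notna().to_numpy()
    n_train = int(mask.sum())
    if n_train < 2:
        raise ValueError(f"drug {drug!r}: need >= 2 screened lines, have {n_train}")
    X = train_expr.loc[:, train_expr.columns[mask]].to_numpy().T  # samples x genes
    y = auc.to_numpy(dtype=float)[mask]
    genes = list(train_expr.index)

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("drug %s: dropping %d zero-variance genes (e.g. %s)",
                       drug, len(dropped), dropped[:3])
        X = X[:, keep]
        genes = [g for g, k in zip(genes, keep) if k]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError(f"drug {drug!r}: no usable (non-constant) genes")

    if standardize:
        mean = X.mean(axis=0)
        scale = sd
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    intercept = float(y.mean())
    yc = y - intercept

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    if lam_mode == "loo":
        grid = _DEFAULT_LAMBDA_GRID if lam_grid is None else np.asarray(lam_grid)
        lam = _loo_lambda(U, s, yc, grid)
    elif lam_mode != "fixed":
        raise ValueError(f"lam_mode must be 'loo' or 'fixed', got {lam_mode!r}")
    coef = Vt.T @ ((s / (s**2 + lam)) * (U.T @ yc))

    return RidgeModel(drug=drug, genes=genes, coef=coef, intercept=intercept,
                      lam=float(lam), n_train=n_train, gene_mean=mean,
                      gene_scale=scale, small_n=n_train < SMALL_TRAIN_N)


def fit_models(train_expr: pd.DataFrame, screen: pd.DataFrame,
               lam_mode: str = "loo", lam: float = 1.0,
               lam_grid: np.ndarray | None = None) -> dict[str, RidgeModel]:
    """Fit ridge models for every drug in the (coverage-filtered) screen."""
    return {
        drug: fit_ridge(train_expr, screen[drug], drug=drug,
                        lam_mode=lam_mode, lam=lam, lam_grid=lam_grid)
        for drug in screen.columns
    }


def impute(model: RidgeModel, test_expr: pd.DataFrame) -> pd.Series:
    """Score samples with a fitted model: ``intercept + beta^T x_std``."""
    missing = [g for g in model.genes if g not in test_expr.index]
    if missing:
        raise ValueError(
            f"test expression lacks {len(missing)} model genes "
            f"(e.g. {missing[:3]}); harmonize against the training panel first")
    X = test_expr.loc[model.genes].to_numpy().T
    Xs = (X - model.gene_mean) / model.gene_scale
    return pd.Series(model.intercept + Xs @ model.coef,
                     index=test_expr.columns, name=model.drug)


def impute_panel(models: dict[str, RidgeModel],
                 test_expr: pd.DataFrame) -> pd.DataFrame:
    """Samples x drugs imputed AUC for a set of fitted models."""
    return pd.DataFrame({d: impute(m, test_expr) for d, m in models.items()})


def gene_response_correlation(expr: pd.DataFrame, imputed: pd.DataFrame,
                              drug: str) -> pd.DataFrame:
    """Per-gene Spearman correlation against one drug's imputed AUC.

    Returns a DataFrame (gene, r, p, q) with BH adjustment across all
    non-degenerate genes for this drug; constant genes get NaN with a
    warning. Requires at least 4 samples.
    """
    return spearman_table(expr, imputed[drug])


def spearman_table(expr: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    """Spearman r/p/q of every gene row against a per-sample response vector."""
    response = response.reindex(expr.columns)
    n = len(response)
    if n < 4:
        raise ValueError(f"need >= 4 samples, have {n}")
    vals = expr.to_numpy()
    resp_rank = stats.rankdata(response.to_numpy())
    gene_rank = stats.rankdata(vals, axis=1)

    gr = gene_rank - gene_rank.mean(axis=1, keepdims=True)
    rr = resp_rank - resp_rank.mean()
    denom = np.sqrt((gr**2).sum(axis=1) * (rr**2).sum())
    const = denom == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s); "
                      "correlation undefined, reported as NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (gr @ rr) / denom
    r = np.clip(r, -1.0, 1.0)
    # t-approximation p-value on the rank correlation (tie-aware via midranks)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[const] = np.nan

    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return pd.DataFrame({"gene": expr.index, "r": r, "p": p, "q": q})
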