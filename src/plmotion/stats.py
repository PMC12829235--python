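"""Clip-level inference: ordinal regression, Spearman, polynomial AIC.

The clip statistic (maximum pleural-line lateral movement, mm) is related
to an ordered visual lung-sliding grade through a proportional-odds
cumulative-logit model

    P(Y <= k | x) = logistic(c_k - beta * x),

whose exp(beta) is the odds ratio per mm of movement, and to a continuous
overdistention percentage through quadratic least squares with AIC-based
model comparison (Delta-AIC referenced to the best model on a common
dataset). Classification performance of the ordinal model is summarized by
a confusion matrix and balanced accuracy (unweighted mean per-class
recall), with the predicted class taken as the probability argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import spearmanr
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .simulate import SLIDING_CATEGORIES

__all__ = [
    "OrdinalFit",
    "PolyFit",
    "fit_proportional_odds",
    "predict_categories",
    "predict_and_confuse",
    "spearman",
    "fit_quadratic",
    "fit_polynomial",
    "delta_aic",
    "load_cohort_table",
]


@dataclass(frozen=True)
class OrdinalFit:
    """Fitted proportional-odds model for an ordinal outcome on one predictor."""

    beta: float
    se_beta: float
    cutpoints: np.ndarray
    loglik: float
    n: int
    categories: tuple[str, ...]
    converged: bool

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def ci_beta(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for the slope."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.beta - z * self.se_beta, self.beta + z * self.se_beta

    def category_probs(self, x: np.ndarray) -> np.ndarray:
        """P(Y = k | x) for each observation and category (rows sum to 1)."""
        x = np.asarray(x, dtype=float)
        cum = expit(self.cutpoints[None, :] - self.beta * x[:, None])
        cum = np.hstack([np.zeros((x.size, 1)), cum, np.ones((x.size, 1))])
        return np.diff(cum, axis=1)


def _as_codes(y, categories: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(y, pd.Series) and isinstance(y.dtype, pd.CategoricalDtype):
        cats = tuple(str(c) for c in y.cat.categories)
        return y.cat.codes.to_numpy(), cats
    y = np.asarray(y)
    if categories is None:
        levels = sorted(np.unique(y).tolist())
        lut = {k: i for i, k in enumerate(levels)}
        return np.array([lut[v] for v in y]), tuple(str(k) for k in levels)
    cats = tuple(str(c) for c in categories)
    if np.issubdtype(y.dtype, np.integer) and set(np.unique(y)) <= set(range(len(cats))):
        # already category codes against the supplied label order
        return y.astype(int), cats
    lut = {c: i for i, c in enumerate(categories)}
    return np.array([lut[v] for v in y]), cats


def fit_proportional_odds(
    x, y, categories: Sequence[str] | None = None
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of ordinal ``y`` on ``x``.

    ``y`` may be an ordered pandas Categorical, integer codes, or labels
    plus an explicit ``categories`` order. Non-convergence (e.g. complete
    separation) is flagged on the returned fit and warned about, never
    silently ignored.
    """
    x = np.asarray(x, dtype=float)
    codes, cats = _as_codes(y, categories)
    observed = np.unique(codes)
    if observed.size < 2:
        raise ValueError("need at least 2 observed categories")
    if x.size <= observed.size:  # parameters: slope + (K-1) cutpoints
        raise ValueError("need more observations than model parameters")

    model = OrderedModel(codes, x[:, None], distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", disp=0, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", False))
    beta = float(res.params[0])
    se = float(res.bse[0])
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    if not converged or not np.isfinite(se) or abs(beta) > 50:
        converged = False
        warnings.warn(
            "proportional-odds fit did not converge (possible complete separation); "
            "estimates are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return OrdinalFit(
        beta=beta,
        se_beta=se,
        cutpoints=np.asarray(thresholds, dtype=float),
        loglik=float(res.llf),
        n=int(x.size),
        categories=cats,
        converged=converged,
    )


def proportional_odds_loglik(
    x, codes, beta: float, cutpoints: np.ndarray
) -> float:
    """Log-likelihood of arbitrary (beta, cutpoints) under the model.

    Useful for checking MLE optimality against the generating parameters.
    """
    x = np.asarray(x, dtype=float)
    codes = np.asarray(codes)
    cuts = np.asarray(cutpoints, dtype=float)
    cum = expit(cuts[None, :] - beta * x[:, None])
    cum = np.hstack([np.zeros((x.size, 1)), cum, np.ones((x.size, 1))])
    probs = np.diff(cum, axis=1)
    p = probs[np.arange(x.size), codes]
    return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def predict_categories(fit: OrdinalFit, x) -> np.ndarray:
    """Predicted category index per observation (probability argmax)."""
    return fit.category_probs(np.asarray(x, dtype=float)).argmax(axis=1)


def predict_and_confuse(
    fit: OrdinalFit, x, y_true, categories: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Confusion matrix, per-class recall and balanced accuracy.

    Matrix rows are the true categories, columns the predicted ones.
    Balanced accuracy is the unweighted mean recall over classes present
    in ``y_true``; absent classes are excluded with a warning.
    """
    if not fit.converged:
        raise ValueError("cannot evaluate predictions from a non-converged fit")
    codes_true, cats = _as_codes(y_true, categories or fit.categories)
    pred = predict_categories(fit, x)
    k = len(cats)
    matrix = np.zeros((k, k), dtype=int)
    np.add.at(matrix, (codes_true, pred), 1)
    cm = pd.DataFrame(matrix, index=list(cats), columns=list(cats))
    cm.index.name = "true"
    cm.columns.name = "predicted"

    row_totals = matrix.sum(axis=1)
    recall = pd.Series(
        np.divide(np.diag(matrix), row_totals, where=row_totals > 0, out=np.full(k, np.nan)),
        index=list(cats),
        name="recall",
    )
    present = row_totals > 0
    if not present.all():
        missing = [c for c, p in zip(cats, present) if not p]
        warnings.warn(
            f"classes absent from y_true excluded from balanced accuracy: {missing}",
            RuntimeWarning,
            stacklevel=2,
        )
    balanced = float(recall[present].mean())
    return cm, recall, balanced


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    return float(spearmanr(x, y).statistic)


@dataclass(frozen=True)
class PolyFit:
    """Least-squares polynomial fit with the package's AIC convention.

    AIC = n * ln(RSS / n) + 2k with k = (number of coefficients) + 1 for
    the error variance (k = 4 for a quadratic). The additive constant of
    the Gaussian likelihood is dropped, so only AIC *differences* between
    fits on the same observations are meaningful.
    """

    beta: tuple[float, ...]
    r_squared: float
    adj_r_squared: float
    aic: float
    n: int
    k: int


def fit_polynomial(x, y, degree: int) -> PolyFit:
    """OLS fit of y on [1, x, ..., x^degree]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    k = degree + 2  # coefficients + error variance
    if x.size < k:
        raise ValueError(f"need at least {k} observations for degree {degree}")
    if np.unique(x).size < degree + 1:
        raise ValueError(f"need >= {degree + 1} distinct x values")
    design = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    n = x.size
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return PolyFit(
        beta=tuple(float(b) for b in res.params),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        aic=float(aic),
        n=n,
        k=k,
    )


def fit_quadratic(x, y) -> PolyFit:
    """Quadratic least squares: y = b0 + b1*x + b2*x^2."""
    return fit_polynomial(x, y, degree=2)


def delta_aic(fits: Sequence[PolyFit] | Sequence[float]) -> np.ndarray:
    """Delta-AIC per model: each AIC minus the smallest AIC in the set.

    All fits must be on the identical observation set (checked via n when
    PolyFit objects are passed); raw AIC floats are accepted for printed
    comparisons.
    """
    if len(fits) < 2:
        raise ValueError("delta_aic needs at least 2 models")
    if isinstance(fits[0], PolyFit):
        ns = {f.n for f in fits}  # type: ignore[union-attr]
        if len(ns) != 1:
            raise ValueError("all models must be fitted on the same observations")
        aics = np.array([f.aic for f in fits], dtype=float)  # type: ignore[union-attr]
    else:
        aics = np.asarray(fits, dtype=float)
    return aics - aics.min()


def load_cohort_table(path, categories: Sequence[str] = SLIDING_CATEGORIES) -> pd.DataFrame:
    """Read a clip-level cohort CSV for the inference layer.

    Requires ``clip_id`` and ``pl_movement_mm`` columns; if present,
    ``sliding_category`` becomes an ordered categorical in the given order.
    For clinical tables ``od_percent`` is a percentage in [0, 100];
    synthetic cohorts may exceed that range by construction.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"clip_id", "pl_movement_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if "sliding_category" in df.columns:
        df["sliding_category"] = pd.Categorical(
            df["sliding_category"], categories=list(categories), ordered=True
        )
    return df
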