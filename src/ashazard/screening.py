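"""Repeated univariate screening and multicollinearity filtering.

Candidate predictors are screened in two stages, repeated over many random
train/test splits to wash out split-to-split noise:

1. a univariate likelihood-ratio test of the single-covariate logistic
   model against the intercept-only model (the type-II ANOVA test for a
   one-variable logistic fit); variables with mean p < 0.05 survive;
2. variance-inflation-factor filtering among the surviving *continuous*
   variables: VIF = 1/(1−R²) of each variable regressed on the others,
   removing the worst offender above 10 and recomputing until all remaining
   mean VIFs are ≤ 10.  Categorical indicators are exempt.

The classical linear R² and the deviance-based pseudo-R² = 1 − exp(−D/n)
(D the Gaussian likelihood-ratio statistic of the auxiliary regression) are
both available; the two coincide algebraically for a Gaussian auxiliary
model, since D = n·ln(TSS/RSS) gives 1 − exp(−D/n) = 1 − RSS/TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .preprocess import BinaryDataset, stratified_split

P_CUTOFF = 0.05
VIF_CUTOFF = 10.0


class SeparationWarning(UserWarning):
    """The univariate logistic fit showed (quasi-)complete separation."""


@dataclass(frozen=True)
class ScreeningResult:
    """Per-variable mean p, mean VIF and retention flag at one threshold."""

    threshold: float
    n_repeats: int
    table: pd.DataFrame  # index: variable; columns: kind, mean_p, mean_vif, retained

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def _null_llf(y: np.ndarray) -> float:
    n = y.size
    k = y.sum()
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def univariate_p(feature, labels) -> float:
    """Likelihood-ratio p-value of a single covariate (or indicator set).

    ``feature`` may be 1-D (1 df) or an n×k indicator block (k df).  The
    statistic is twice the log-likelihood gain of the covariate model over
    the intercept-only model, referred to a χ² with df = number of columns.
    A constant feature carries zero deviance and returns p = 1.  Separation
    is reported via :class:`SeparationWarning`; the p-value is still the
    one implied by the (diverged) likelihood.
    """
    X = np.asarray(feature, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    df = X.shape[1]
    if np.all(X.std(axis=0) == 0):
        return 1.0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, method="newton", maxiter=50
            )
            llf = res.llf
            sep = not res.mle_retvals.get("converged", True)
        except Exception:  # singular Hessian under separation
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, method="bfgs", maxiter=200
            )
            llf = res.llf
            sep = True
        sep = sep or any("erfectSeparation" in str(w.category) for w in caught)
    D = 2.0 * (llf - _null_llf(y))
    p = float(sps.chi2.sf(max(D, 0.0), df))
    if sep:
        warnings.warn("perfect or quasi-separation in univariate fit", SeparationWarning)
    return p


def _aux_r2(X: np.ndarray, j: int) -> float:
    """R² of column j regressed (with intercept) on the remaining columns."""
    others = np.delete(X, j, axis=1)
    target = X[:, j]
    design = np.column_stack([np.ones(X.shape[0]), others])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    tss = float(((target - target.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


def vif(feature_matrix, target_index: int, variant: str = "linear") -> float:
    """Variance inflation factor 1/(1−R²) of one column against the rest.

    ``variant='linear'`` uses the classical coefficient of determination of
    the auxiliary linear regression; ``variant='deviance'`` routes through
    the pseudo-R² 1 − exp(−D/n) with D the Gaussian likelihood-ratio
    statistic of the same auxiliary regression (numerically identical for
    this model family).  Exact collinearity returns +inf.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two features")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than features")
    r2 = _aux_r2(X, target_index)
    if variant == "deviance":
        # D = n·ln(TSS/RSS); guard the log for exact collinearity
        if r2 >= 1.0 - 1e-15:
            return float("inf")
        D = -X.shape[0] * np.log1p(-r2)
        r2 = 1.0 - np.exp(-D / X.shape[0])
    elif variant != "linear":
        raise ValueError(f"unknown VIF variant {variant!r}")
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_from_r2(r2: float) -> float:
    """The bare VIF formula, exposed for configuration checks."""
    if r2 >= 1.0:
        return float("inf")
    return 1.0 / (1.0 - r2)


def screen(
    dataset: BinaryDataset,
    threshold: float,
    n_repeats: int = 1000,
    base_seed: int = 0,
    train_fraction: float = 0.8,
    p_cutoff: float = P_CUTOFF,
    vif_cutoff: float = VIF_CUTOFF,
    vif_variant: str = "linear",
) -> ScreeningResult:
    """Averaged univariate-p / VIF retention decision at one threshold.

    For each of ``n_repeats`` repeats (repeat i seeded ``base_seed + i``) a
    fresh stratified 80/20 split is drawn and univariate p-values computed
    on the training part.  Variables whose mean p across repeats is below
    ``p_cutoff`` enter the VIF stage, where mean VIFs (same training
    subsets) are filtered iteratively: while the largest mean VIF among the
    retained continuous variables exceeds ``vif_cutoff``, that variable is
    dropped and the means recomputed.  Deterministic for a fixed base seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = dataset.labels[threshold]
    names = list(dataset.feature_names)
    splits = [
        stratified_split(y, train_fraction, seed=base_seed + i, threshold=threshold)
        for i in range(n_repeats)
    ]
    pvals = np.empty((n_repeats, len(names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for i, sp in enumerate(splits):
            tr = sp.train_indices
            for j in range(len(names)):
                pvals[i, j] = univariate_p(dataset.features[tr, j], y[tr])
    mean_p = pvals.mean(axis=0)

    candidates = [n for n, p in zip(names, mean_p) if p < p_cutoff]
    cont = [n for n in candidates if dataset.feature_kinds.get(n) == "continuous"]
    mean_vif: dict[str, float] = {}
    dropped_vif: dict[str, float] = {}
    while len(cont) >= 2:
        cols = [names.index(n) for n in cont]
        vifs = np.zeros((n_repeats, len(cont)))
        for i, sp in enumerate(splits):
            sub = dataset.features[np.ix_(sp.train_indices, cols)]
            for j in range(len(cont)):
                vifs[i, j] = vif(sub, j, variant=vif_variant)
        mv = vifs.mean(axis=0)
        mean_vif = dict(zip(cont, mv))
        worst = int(np.argmax(mv))
        if mv[worst] > vif_cutoff:
            dropped_vif[cont[worst]] = float(mv[worst])
            cont.pop(worst)
        else:
            break
    if len(cont) == 1:
        mean_vif = {cont[0]: 1.0}

    rows = []
    for j, name in enumerate(names):
        kind = dataset.feature_kinds.get(name, "continuous")
        mv = mean_vif.get(name, dropped_vif.get(name, np.nan))
        if kind == "categorical":
            retained = mean_p[j] < p_cutoff
        else:
            retained = name in cont and mean_p[j] < p_cutoff
        rows.append((name, kind, mean_p[j], mv, bool(retained)))
    table = pd.DataFrame(
        rows, columns=["variable", "kind", "mean_p", "mean_vif", "retained"]
    ).set_index("variable")
    return ScreeningResult(threshold=threshold, n_repeats=n_repeats, table=table)


def screening_report(results: list[ScreeningResult]) -> pd.DataFrame:
    """Wide variable × threshold report of mean p / VIF with retention flags."""
    frames = {}
    for r in results:
        t = r.table.rename(
            columns={
                "mean_p": f"p_{r.threshold:g}",
                "mean_vif": f"vif_{r.threshold:g}",
                "retained": f"retained_{r.threshold:g}",
            }
        ).drop(columns="kind")
        frames[r.threshold] = t
    return pd.concat(frames.values(), axis=1)
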