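"""Ensemble stepwise-AIC logistic regression with calibration gating.

The modelling engine of the package.  For one exceedance threshold the
procedure is:

1. draw a stratified 80/20 train/test split;
2. run both-direction stepwise selection on the training data, adding or
   removing single variables while the Akaike information criterion
   AIC = 2k − 2·ln(L) improves;
3. score the selected model on the held-out test data with the
   Hosmer–Lemeshow goodness-of-fit test (decile-of-risk groups, χ² with
   g − 2 df); the run passes the gate iff p > 0.05;
4. repeat (default 1000 times), then group passing runs by their selected
   variable combination, average coefficients within each combination and
   attach the mean held-out AUC plus a whole-data AUC computed from the
   averaged coefficients.

The final model is the combination with the largest mean held-out AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from scipy import stats as sps

from .preprocess import BinaryDataset, stratified_split

HL_ALPHA = 0.05


class UndefinedAUCError(ValueError):
    """AUC requested for single-class labels."""


@dataclass(frozen=True)
class FittedModel:
    """A maximum-likelihood logistic fit on a named variable combination."""

    variables: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    log_likelihood: float
    converged: bool

    @property
    def aic(self) -> float:
        k = 1 + len(self.variables)
        return 2.0 * k - 2.0 * self.log_likelihood

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coefficients


@dataclass(frozen=True)
class RocCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    auc: float


@dataclass(frozen=True)
class CombinationStats:
    variables: tuple[str, ...]
    count: int
    intercept_mean: float
    intercept_sd: float
    coef_mean: np.ndarray
    coef_sd: np.ndarray
    mean_test_auc: float
    whole_data_auc: float


@dataclass(frozen=True)
class EnsembleSummary:
    threshold: float
    n_runs: int
    n_passed: int
    n_diverged: int
    combinations: tuple[CombinationStats, ...] = field(default_factory=tuple)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "combination": ", ".join(c.variables) or "(intercept only)",
                "count": c.count,
                "mean_test_auc": c.mean_test_auc,
                "whole_data_auc": c.whole_data_auc,
            }
            for c in self.combinations
        ]
        return pd.DataFrame(rows).sort_values(
            ["mean_test_auc", "count"], ascending=False, ignore_index=True
        )


@dataclass(frozen=True)
class FinalModel:
    """The selected combination with ensemble-averaged coefficients."""

    threshold: float
    variables: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    intercept_sd: float
    coef_sd: np.ndarray
    mean_test_auc: float
    whole_data_auc: float
    count: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return special.expit(self.intercept + np.asarray(X, float) @ self.coefficients)


def fit_logistic(X, y, variables=None) -> FittedModel:
    """Maximum-likelihood logistic regression with a free intercept.

    ``X`` may have zero columns (intercept-only model).  Separation or
    non-convergence is reported through the ``converged`` flag rather than
    an exception; the coefficients are then the optimizer's last iterate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if variables is None:
        variables = tuple(f"x{i}" for i in range(X.shape[1]))
    variables = tuple(variables)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    design = np.column_stack([np.ones(X.shape[0]), X])
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=60)
        except Exception:
            res = sm.Logit(y, design).fit(disp=0, method="bfgs", maxiter=300)
            converged = False
        converged = (
            converged
            and res.mle_retvals.get("converged", True)
            and not any("erfectSeparation" in str(w.category) for w in caught)
        )
    params = np.asarray(res.params, dtype=float)
    return FittedModel(
        variables=variables,
        intercept=float(params[0]),
        coefficients=params[1:],
        log_likelihood=float(res.llf),
        converged=bool(converged),
    )


def predict_prob(model: FittedModel, x, variables=None) -> np.ndarray | float:
    """Logistic probability for covariate vector(s) on the model's scale.

    If ``variables`` is given it must match the model's combination, which
    guards against silently feeding columns in the wrong order.
    """
    if variables is not None and tuple(variables) != model.variables:
        raise KeyError(
            f"covariate names {tuple(variables)} do not match model {model.variables}"
        )
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1 and len(model.variables) == x.size
    p = special.expit(model.linear_predictor(x if not scalar else x[None, :]))
    return float(p[0]) if scalar else p


def stepwise_aic(
    X,
    y,
    variables,
    direction: str = "both",
    start: str = "full",
) -> FittedModel:
    """Both-direction stepwise selection minimising AIC.

    Starting from the full screened model (or the intercept-only model with
    ``start='null'``), every single-variable removal and addition is
    evaluated each round and the move with the lowest AIC is taken while it
    improves on the current model.  Ties break toward fewer variables, then
    lexicographically, which makes the search deterministic.  Terminates at
    a model no single move can improve.
    """
    X = np.asarray(X, dtype=float)
    variables = list(variables)
    if not variables:
        raise ValueError("screened variable set must be non-empty")
    if X.shape[1] != len(variables):
        raise ValueError("X columns must align with variable names")
    col = {v: i for i, v in enumerate(variables)}
    cache: dict[frozenset, FittedModel] = {}

    def fit(combo: frozenset) -> FittedModel:
        if combo not in cache:
            names = tuple(sorted(combo))
            cache[combo] = fit_logistic(
                X[:, [col[v] for v in names]], y, variables=names
            )
        return cache[combo]

    current = frozenset(variables) if start == "full" else frozenset()
    if start not in ("full", "null"):
        raise ValueError("start must be 'full' or 'null'")
    best = fit(current)
    while True:
        moves: list[tuple[float, int, tuple, frozenset]] = []
        if direction in ("both", "backward"):
            for v in sorted(current):
                combo = current - {v}
                m = fit(combo)
                moves.append((m.aic, len(combo), tuple(sorted(combo)), combo))
        if direction in ("both", "forward"):
            for v in sorted(set(variables) - current):
                combo = current | {v}
                m = fit(combo)
                moves.append((m.aic, len(combo), tuple(sorted(combo)), combo))
        if not moves:
            break
        moves.sort()
        aic, _, _, combo = moves[0]
        if aic < best.aic - 1e-10:
            current, best = combo, fit(combo)
        else:
            break
    return best


def hosmer_lemeshow(probs, y, n_groups: int = 10) -> tuple[float, float]:
    """Hosmer–Lemeshow χ² statistic and p-value (decile-of-risk grouping).

    Records are sorted by predicted probability (stable sort) and cut into
    ``n_groups`` near-equal groups; the statistic sums
    (O − E)² / (E·(1 − E/m)) over groups, referred to χ² with g − 2 df.
    Degenerate groups (E = 0 or E = m) have their denominator floored at
    1e−10 and trigger a warning.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if probs.size < 2 * n_groups:
        raise ValueError("need at least 2 observations per group")
    order = np.argsort(probs, kind="stable")
    stat = 0.0
    degenerate = False
    for grp in np.array_split(order, n_groups):
        m = grp.size
        O = float(y[grp].sum())
        E = float(probs[grp].sum())
        denom = E * (1.0 - E / m)
        if denom <= 0.0:
            degenerate = True
            denom = max(denom, 1e-10)
        stat += (O - E) ** 2 / denom
    if degenerate:
        warnings.warn("degenerate Hosmer-Lemeshow group (E=0 or E=m)", UserWarning)
    p = float(sps.chi2.sf(stat, n_groups - 2))
    return float(stat), p


def roc_auc(scores, y) -> RocCurve:
    """ROC curve by sweeping all distinct score cutoffs; AUC by trapezoid.

    Classification at cutoff c is positive iff score ≥ c.  The trapezoidal
    integral over the stepwise (FPR, TPR) path equals the probability that
    a random positive outscores a random negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes required for a ROC curve")

    cutoffs = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    pos_sorted = np.sort(scores[y == 1])
    neg_sorted = np.sort(scores[y == 0])
    # count of scores >= c via searchsorted on the sorted class scores
    tp = n_pos - np.searchsorted(pos_sorted, cutoffs, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, cutoffs, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    acc = (tp + (n_neg - fp)) / (n_pos + n_neg)

    # integration path: cutoffs descending, with a virtual (0, 0) endpoint
    desc = np.unique(scores)[::-1]
    tpr = (n_pos - np.searchsorted(pos_sorted, desc, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(neg_sorted, desc, side="left")) / n_neg
    fpr_path = np.concatenate([[0.0], fpr, [1.0]])
    tpr_path = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr_path, fpr_path))
    return RocCurve(cutoffs, sens, spec, acc, auc)


def run_ensemble(
    dataset: BinaryDataset,
    threshold: float,
    screened,
    n_runs: int = 1000,
    base_seed: int = 0,
    train_fraction: float = 0.8,
    hl_groups: int = 10,
    hl_alpha: float = HL_ALPHA,
    start: str = "full",
) -> EnsembleSummary:
    """Run the stepwise/HL ensemble at one threshold.

    Run i (seeded ``base_seed + i``) draws a fresh stratified split, runs
    stepwise-AIC on the training part and gates the selected model on the
    Hosmer–Lemeshow p-value computed on the held-out part (pass iff
    p > ``hl_alpha``).  Non-convergent fits are tallied separately and
    excluded.  Passing runs are grouped by unordered variable combination;
    coefficients and held-out AUCs are averaged within groups and a
    whole-data AUC is computed once per combination from its mean
    coefficients.  Deterministic for a fixed base seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    screened = list(screened)
    y = dataset.labels[threshold]
    Xall = dataset.columns(screened)
    col = {v: i for i, v in enumerate(screened)}

    records: dict[tuple[str, ...], list] = {}
    n_passed = 0
    n_diverged = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n_runs):
            sp = stratified_split(y, train_fraction, seed=base_seed + i, threshold=threshold)
            tr, te = sp.train_indices, sp.test_indices
            model = stepwise_aic(Xall[tr], y[tr], screened, start=start)
            if not model.converged:
                n_diverged += 1
                continue
            idx = [col[v] for v in model.variables]
            probs_te = special.expit(model.linear_predictor(Xall[np.ix_(te, idx)]))
            _, hl_p = hosmer_lemeshow(probs_te, y[te], n_groups=hl_groups)
            if hl_p <= hl_alpha:
                continue
            n_passed += 1
            if np.unique(y[te]).size == 2:
                test_auc = roc_auc(probs_te, y[te]).auc
            else:
                test_auc = np.nan
            records.setdefault(model.variables, []).append(
                (model.intercept, model.coefficients, test_auc)
            )

    combos = []
    for variables, rows in records.items():
        intercepts = np.array([r[0] for r in rows])
        coefs = np.array([r[1] for r in rows]).reshape(len(rows), len(variables))
        aucs = np.array([r[2] for r in rows])
        mean_coef = coefs.mean(axis=0)
        idx = [col[v] for v in variables]
        whole_probs = special.expit(intercepts.mean() + Xall[:, idx] @ mean_coef)
        if len(variables) == 0:
            whole_auc = 0.5
        else:
            whole_auc = roc_auc(whole_probs, y).auc
        combos.append(
            CombinationStats(
                variables=variables,
                count=len(rows),
                intercept_mean=float(intercepts.mean()),
                intercept_sd=float(intercepts.std(ddof=0)),
                coef_mean=mean_coef,
                coef_sd=coefs.std(axis=0, ddof=0),
                mean_test_auc=float(np.nanmean(aucs)) if not np.all(np.isnan(aucs)) else np.nan,
                whole_data_auc=float(whole_auc),
            )
        )
    if not combos:
        warnings.warn(
            f"no run passed the Hosmer-Lemeshow gate at threshold {threshold}",
            UserWarning,
        )
    return EnsembleSummary(
        threshold=threshold,
        n_runs=n_runs,
        n_passed=n_passed,
        n_diverged=n_diverged,
        combinations=tuple(combos),
    )


def select_final(summary: EnsembleSummary) -> FinalModel:
    """Pick the combination with the largest mean held-out AUC.

    Ties break toward the more frequent combination, then the smaller one,
    then lexicographic order of the variable names.
    """
    if not summary.combinations:
        raise ValueError("empty ensemble summary: no passing runs")

    def key(c: CombinationStats):
        auc = -np.inf if np.isnan(c.mean_test_auc) else c.mean_test_auc
        return (-auc, -c.count, len(c.variables), c.variables)

    best = min(summary.combinations, key=key)
    return FinalModel(
        threshold=summary.threshold,
        variables=best.variables,
        intercept=best.intercept_mean,
        coefficients=best.coef_mean,
        intercept_sd=best.intercept_sd,
        coef_sd=best.coef_sd,
        mean_test_auc=best.mean_test_auc,
        whole_data_auc=best.whole_data_auc,
        count=best.count,
    )


def coefficient_report(finals: list[FinalModel]) -> pd.DataFrame:
    """Variable × threshold table of mean coefficients and their sds."""
    frames = {}
    for fm in finals:
        rows = {"Intercept": (fm.intercept, fm.intercept_sd)}
        for v, c, s in zip(fm.variables, fm.coefficients, fm.coef_sd):
            rows[v] = (c, s)
        frames[fm.threshold] = pd.DataFrame(
            rows, index=[f"coef_{fm.threshold:g}", f"sd_{fm.threshold:g}"]
        ).T
    return pd.concat(frames.values(), axis=1)
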