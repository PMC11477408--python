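"""Diagnostic evaluation of sIgE analytes against oral-food-challenge
outcomes.

Single analytes are scored by ROC/AUC (AUC computed as the tie-corrected
rank statistic, equivalently the probability a random allergic subject
outranks a random tolerant one with ties counting half).  Multi-analyte
panels are logistic-regression fits over log10(sIgE + 0.01) predictors;
for each panel size the subset minimising AIC is found by exhaustive
enumeration, with trajectories reported both with and without the
challenged fish's own extract.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .serology import log_transform

logger = logging.getLogger(__name__)

SEPARATION_NORM = 30.0  # ||beta|| beyond this flags complete separation


@dataclass
class RocResult:
    """ROC curve (threshold sweep) and its AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC analysis of a continuous score against binary labels.

    AUC is the rank statistic P(score_pos > score_neg) + 0.5 P(tie);
    the curve sweeps thresholds over the unique scores (predict positive
    when score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    sens = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    spec = np.array([(scores[labels == 0] < t).mean() for t in thresholds])
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=float(auc))


def trapezoid_auc(roc: RocResult) -> float:
    """Trapezoidal area under the ROC curve (1 - specificity vs sensitivity)."""
    fpr = 1.0 - roc.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(roc.sensitivity[order], fpr[order]))


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit (IRLS)."""

    predictors: list[str]
    coefficients: np.ndarray  # [intercept, beta_1..beta_k]
    log_likelihood: float
    converged: bool
    n_iter: int
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return 2.0 * (len(self.predictors) + 1) - 2.0 * self.log_likelihood


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_fit(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    An intercept is always included.  Convergence requires the maximum
    coefficient change to fall below ``tol``; step-halving guards each
    update so the log-likelihood never decreases.  Complete separation
    (diverging coefficient norm) stops the iteration with
    ``converged=False`` and a warning rather than an error.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y).astype(float)
    if set(np.unique(y)) == {0.0} or set(np.unique(y)) == {1.0}:
        raise ValueError("outcome is constant; logistic fit undefined")
    n, k = Xm.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Xm])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        # name the offending columns by successive-rank probing
        collinear = []
        for j in range(1, k + 1):
            sub = design[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                collinear.append(names[j - 1])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {collinear}")

    beta = np.zeros(k + 1)
    llf = _log_likelihood(design, y, beta)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        wd = design * w[:, None]
        try:
            new_beta = np.linalg.solve(design.T @ wd, wd.T @ z)
        except np.linalg.LinAlgError:
            break
        step = new_beta - beta
        # step-halving: accept only non-decreasing log-likelihood
        scale = 1.0
        new_llf = _log_likelihood(design, y, beta + step)
        while new_llf < llf and scale > 1e-6:
            scale /= 2.0
            new_llf = _log_likelihood(design, y, beta + scale * step)
        beta = beta + scale * step
        delta = float(np.max(np.abs(scale * step)))
        llf = new_llf
        if np.linalg.norm(beta) > SEPARATION_NORM:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    if separated:
        warnings.warn(
            "complete or quasi-complete separation detected (diverging coefficients); "
            "fit flagged non-converged",
            stacklevel=2,
        )
    fitted = 1.0 / (1.0 + np.exp(-(design @ beta)))
    return LogisticFit(
        predictors=names,
        coefficients=beta,
        log_likelihood=llf,
        converged=converged and not separated,
        n_iter=it,
        fitted=fitted,
    )


@dataclass
class SubsetTrajectory:
    """Best predictor subset (by AIC) and its in-sample AUC per size."""

    sizes: list[int]
    best_subsets: list[tuple[str, ...]]
    aics: list[float]
    aucs: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "subset": [",".join(s) for s in self.best_subsets],
                "aic": self.aics,
                "auc": self.aucs,
            }
        )


def best_subsets(X: pd.DataFrame, y: np.ndarray, max_size: int | None = None) -> SubsetTrajectory:
    """Exhaustive best-subset logistic selection under AIC.

    For each subset size s <= ``max_size``, every size-s predictor
    combination is fitted and the AIC-minimal one kept (ties break on
    lexicographic predictor names).  Limited to 15 predictors (2^15 - 1
    models); screen predictors first beyond that.
    """
    p = X.shape[1]
    if p > 15:
        raise ValueError(f"{p} predictors would need 2^{p}-1 fits; screen predictors first")
    max_size = p if max_size is None else min(max_size, p)
    y = np.asarray(y).astype(int)
    sizes, subsets, aics, aucs = [], [], [], []
    for s in range(1, max_size + 1):
        best: tuple[float, tuple[str, ...], LogisticFit] | None = None
        for combo in itertools.combinations(sorted(X.columns), s):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = logistic_fit(X[list(combo)], y)
            key = (fit.aic, combo)
            if best is None or key < (best[0], best[1]):
                best = (fit.aic, combo, fit)
        assert best is not None
        fit = best[2]
        sizes.append(s)
        subsets.append(best[1])
        aics.append(best[0])
        aucs.append(roc_auc(fit.fitted, y).auc)
    return SubsetTrajectory(sizes=sizes, best_subsets=subsets, aics=aics, aucs=aucs)


@dataclass
class PanelReport:
    """Diagnostic report for one challenged fish."""

    target_fish: str
    n_subjects: int
    n_allergic: int
    single_auc: pd.DataFrame  # analyte, auc
    with_target: SubsetTrajectory
    without_target: SubsetTrajectory
    target_auc: float


def panel_evaluation(
    cohort: CohortTable,
    target_fish: str,
    analytes: list[str] | None = None,
    target_analyte: str | None = None,
    max_size: int | None = None,
) -> PanelReport:
    """Evaluate single analytes and best-subset panels for one OFC fish.

    Subjects with an allergic/tolerant OFC label for ``target_fish`` are
    scored: (i) per-analyte ROC AUC; (ii) AIC best-subset trajectories
    including and excluding the target fish's own extract
    (``target_analyte``, defaulting to the fish name); (iii) the single
    target-extract AUC as the reference line.  Predictors enter the
    logistic fits as log10(sIgE + 0.01).
    """
    if target_fish not in cohort.ofc.columns:
        raise KeyError(f"no OFC outcomes recorded for fish {target_fish!r}")
    target_analyte = target_analyte or target_fish
    analytes = analytes or cohort.analytes
    if target_analyte not in analytes:
        raise KeyError(f"target analyte {target_analyte!r} not among analytes")
    labelled = cohort.ofc[target_fish].isin(["allergic", "tolerant"])
    sige = cohort.sige.loc[labelled, analytes]
    y = (cohort.ofc.loc[labelled, target_fish] == "allergic").to_numpy().astype(int)
    if len(y) < 10:
        logger.warning("only %d OFC-labelled subjects for %s", len(y), target_fish)

    rows = [{"analyte": a, "auc": roc_auc(sige[a].to_numpy(), y).auc} for a in analytes]
    single = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)

    X = log_transform(sige)
    with_target = best_subsets(X, y, max_size=max_size)
    others = [a for a in analytes if a != target_analyte]
    without_target = best_subsets(X[others], y, max_size=max_size)
    target_auc = float(single.loc[single["analyte"] == target_analyte, "auc"].iloc[0])
    return PanelReport(
        target_fish=target_fish,
        n_subjects=len(y),
        n_allergic=int(y.sum()),
        single_auc=single,
        with_target=with_target,
        without_target=without_target,
        target_auc=target_auc,
    )


def cross_validated_auc(
    X: pd.DataFrame, y: np.ndarray, n_folds: int = 5, seed: int = 0
) -> float:
    """Stratified k-fold out-of-sample AUC for one predictor set.

    In-sample AUC of a fitted panel is optimistic; this is the honest
    companion estimate.
    """
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    scores = np.zeros(len(y))
    for f in range(n_folds):
        train, test = folds != f, folds == f
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = logistic_fit(X.loc[train], y[train])
        design = np.column_stack([np.ones(test.sum()), X.loc[test].to_numpy(dtype=float)])
        scores[test] = design @ fit.coefficients
    return roc_auc(scores, y).auc
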