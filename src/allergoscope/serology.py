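"""Serological sIgE analysis: sensitization filtering, correlation
structure across analytes, within- vs between-group comparison of
fish-pair correlations, and the association between allergen-expression
correlation and sIgE correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

logger = logging.getLogger(__name__)

SENSITIZATION_CUTOFF = 0.35  # kUA/L; conventional sIgE positivity cutoff


def sensitization_filter(cohort: CohortTable, cutoff: float = SENSITIZATION_CUTOFF) -> CohortTable:
    """Keep subjects sensitized to at least one analyte (sIgE strictly
    above ``cutoff`` kUA/L)."""
    keep = cohort.sige.max(axis=1) > cutoff
    sige = cohort.sige.loc[keep]
    ofc = cohort.ofc.loc[keep] if not cohort.ofc.empty else cohort.ofc
    return CohortTable(sige=sige, ofc=ofc)


def log_transform(values: pd.DataFrame | pd.Series, offset: float = 0.01):
    """log10(x + offset); the conventional variance-stabilising transform
    for sIgE concentrations spanning orders of magnitude."""
    return np.log10(values + offset)


def sige_correlation_matrix(
    cohort: CohortTable,
    analytes: list[str] | None = None,
    transform: str = "raw",
) -> pd.DataFrame:
    """Pairwise Pearson correlation of analyte sIgE values over subjects.

    ``transform`` is "raw" (measured kUA/L) or "log" (log10(x + 0.01)).
    Zero-variance analytes yield undefined (NaN) cells and a warning.
    """
    data = cohort.sige if analytes is None else cohort.sige[analytes]
    if len(data) < 3:
        raise ValueError("need at least 3 subjects for a correlation matrix")
    if transform == "log":
        data = log_transform(data)
    elif transform != "raw":
        raise ValueError("transform must be 'raw' or 'log'")
    constant = [c for c in data.columns if data[c].std(ddof=0) == 0]
    if constant:
        logger.warning("zero-variance analytes (undefined correlations): %s", constant)
    return data.corr(method="pearson")


@dataclass(frozen=True)
class PairedCorrelation:
    """One unordered fish pair with its expression and sIgE correlations."""

    fish_a: str
    fish_b: str
    expr_r: float
    sige_r: float
    relation: str  # "within" | "between"


def pair_correlations(
    expr_corr: pd.DataFrame,
    sige_corr: pd.DataFrame,
    groups: dict[str, str],
) -> list[PairedCorrelation]:
    """Match upper-triangle fish pairs shared by both matrices and label
    each pair within/between by the group assignment.

    Fish present in only one matrix (e.g. an extract with no
    transcriptome) are dropped with a logged list.
    """
    shared = [f for f in expr_corr.index if f in sige_corr.index and f in groups]
    dropped = sorted(set(expr_corr.index) ^ set(sige_corr.index))
    if dropped:
        logger.info("fish dropped from pairing (present in one matrix only): %s", dropped)
    pairs = []
    for i, a in enumerate(shared):
        for b in shared[i + 1 :]:
            relation = "within" if groups[a] == groups[b] else "between"
            pairs.append(
                PairedCorrelation(
                    fish_a=a,
                    fish_b=b,
                    expr_r=float(expr_corr.loc[a, b]),
                    sige_r=float(sige_corr.loc[a, b]),
                    relation=relation,
                )
            )
    return pairs


def within_between_test(pairs: list[PairedCorrelation], value: str = "sige_r") -> tuple[float, float]:
    """Wilcoxon rank-sum of within-group vs between-group pair correlations.

    Returns (W, p) where W is the rank-sum statistic of the within
    sample and p is two-sided.  The exact null distribution is used when
    min(n1, n2) <= 8 and the pooled values carry no ties; otherwise the
    normal approximation with tie and continuity corrections.

    The pair-level correlations are not independent observations (each
    fish joins several pairs); the p-value is descriptive.
    """
    within = [getattr(p, value) for p in pairs if p.relation == "within"]
    between = [getattr(p, value) for p in pairs if p.relation == "between"]
    if not within or not between:
        raise ValueError("need at least one within pair and one between pair")
    pooled = within + between
    has_ties = len(set(pooled)) < len(pooled)
    exact = min(len(within), len(between)) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        within,
        between,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    n1 = len(within)
    w_statistic = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U -> rank-sum W
    return w_statistic, float(res.pvalue)


@dataclass(frozen=True)
class AssociationResult:
    """Least-squares association between two pair-level correlation sets."""

    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n_pairs: int


def expression_sige_association(pairs: list[PairedCorrelation]) -> AssociationResult:
    """Pearson association between expression correlation and sIgE
    correlation over shared fish pairs.

    Two-sided p from the t transform t = r*sqrt((k-2)/(1-r^2)) with
    k - 2 degrees of freedom; the fitted least-squares line is reported.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 shared fish pairs")
    x = np.array([p.expr_r for p in pairs], dtype=float)
    y = np.array([p.sige_r for p in pairs], dtype=float)
    k = len(pairs)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((k - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=k - 2)
    slope, intercept = np.polyfit(x, y, deg=1)
    return AssociationResult(
        pearson_r=r, p_value=float(p), slope=float(slope), intercept=float(intercept), n_pairs=k
    )


def pairs_to_frame(pairs: list[PairedCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fish_a": p.fish_a,
                "fish_b": p.fish_b,
                "expr_r": p.expr_r,
                "sige_r": p.sige_r,
                "relation": p.relation,
            }
            for p in pairs
        ],
        columns=["fish_a", "fish_b", "expr_r", "sige_r", "relation"],
    )
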