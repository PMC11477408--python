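"""Allergen expression profiles from scan hits and a TPM table.

Transcript-level TPMs are pooled per allergen name (all parvalbumin
homologs together, etc.), converted to relative abundances against the
allergen-only total of each sample, isoforms are ranked by descending
TPM, a combined identity/abundance filter retains the "truly" allergenic
set, and samples are clustered on Pearson correlation of their profiles
into a parvalbumin-high and a parvalbumin-low group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .scan import ScanResult

logger = logging.getLogger(__name__)


@dataclass
class AllergenExpressionMatrix:
    """Allergen x sample TPM sums with relative abundances.

    ``tpm_sum`` and ``rel_abundance`` are allergen-name x sample frames;
    ``best_identity`` carries, per allergen and sample, the highest
    identity of any contributing transcript's primary hit.  Samples with
    zero allergen TPM have undefined relative abundances (NaN) and are
    listed in ``flagged_samples``.
    """

    tpm_sum: pd.DataFrame
    rel_abundance: pd.DataFrame
    best_identity: pd.DataFrame
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def allergens(self) -> list[str]:
        return list(self.tpm_sum.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm_sum.columns)


@dataclass(frozen=True)
class IsoformRanking:
    """Transcripts of one allergen in one sample, ranked by TPM."""

    allergen_name: str
    sample: str
    transcript_ids: list[str]
    tpms: list[float]

    @property
    def top_share(self) -> float:
        total = sum(self.tpms)
        return self.tpms[0] / total if total > 0 else float("nan")


@dataclass
class FishGrouping:
    """Two-group sample clustering on allergen-profile correlation."""

    labels: dict[str, str]  # sample -> "PV-high" | "PV-low"
    correlation: pd.DataFrame
    linkage: np.ndarray
    excluded: list[str] = field(default_factory=list)


def aggregate_allergen_expression(scan: ScanResult, tpm_table: pd.DataFrame) -> AllergenExpressionMatrix:
    """Pool transcript TPMs per allergen name using primary assignments.

    Every transcript with a primary hit must be present in the TPM
    table; relative abundances are computed against the total allergen
    TPM of each sample (not the whole transcriptome).
    """
    primary_hits = [h for h in scan.hits if h.is_primary]
    missing = [h.transcript_id for h in primary_hits if h.transcript_id not in tpm_table.index]
    if missing:
        raise KeyError(f"hit transcripts missing from TPM table: {sorted(missing)}")
    samples = list(tpm_table.columns)
    names = sorted({h.allergen_name for h in primary_hits})
    tpm_sum = pd.DataFrame(0.0, index=names, columns=samples)
    best_identity = pd.DataFrame(np.nan, index=names, columns=samples)
    for hit in primary_hits:
        row = tpm_table.loc[hit.transcript_id]
        tpm_sum.loc[hit.allergen_name] += row.to_numpy(dtype=float)
        expressed = row.to_numpy(dtype=float) > 0
        for sample, on in zip(samples, expressed):
            if on:
                cur = best_identity.loc[hit.allergen_name, sample]
                if np.isnan(cur) or hit.identity_pct > cur:
                    best_identity.loc[hit.allergen_name, sample] = hit.identity_pct
    totals = tpm_sum.sum(axis=0)
    flagged = [s for s in samples if totals[s] <= 0]
    if flagged:
        logger.warning("samples with zero allergen TPM: %s", flagged)
    rel = tpm_sum.div(totals.replace(0.0, np.nan), axis=1)
    return AllergenExpressionMatrix(
        tpm_sum=tpm_sum, rel_abundance=rel, best_identity=best_identity, flagged_samples=flagged
    )


def rank_isoforms(scan: ScanResult, tpm_table: pd.DataFrame, allergen_name: str, sample: str) -> IsoformRanking:
    """Rank one allergen's transcripts expressed in one sample by
    descending TPM.

    Transcripts with zero TPM in the sample are not isoforms of that
    sample and are dropped.  Ties break lexicographically by transcript
    id, so the numbering is deterministic.
    """
    transcripts = sorted(
        {h.transcript_id for h in scan.hits if h.is_primary and h.allergen_name == allergen_name}
    )
    transcripts = [t for t in transcripts if t in tpm_table.index]
    if not transcripts:
        raise ValueError(f"no transcripts assigned to {allergen_name!r}")
    if sample not in tpm_table.columns:
        raise KeyError(f"sample {sample!r} not in TPM table")
    pairs = sorted(
        ((tid, float(tpm_table.loc[tid, sample])) for tid in transcripts),
        key=lambda p: (-p[1], p[0]),
    )
    pairs = [p for p in pairs if p[1] > 0]
    if not pairs:
        raise ValueError(f"no transcripts of {allergen_name!r} expressed in {sample!r}")
    return IsoformRanking(
        allergen_name=allergen_name,
        sample=sample,
        transcript_ids=[p[0] for p in pairs],
        tpms=[p[1] for p in pairs],
    )


def filter_true_allergens(
    matrix: AllergenExpressionMatrix,
    id_thresh: float = 70.0,
    abund_thresh: float = 0.01,
    min_samples: int = 3,
) -> list[str]:
    """Retain allergens with credible identity and reproducible abundance.

    An allergen is kept iff its best identity anywhere exceeds
    ``id_thresh`` percent AND its relative abundance exceeds
    ``abund_thresh`` in at least ``min_samples`` samples.
    """
    if len(matrix.samples) < min_samples:
        raise ValueError(
            f"matrix covers {len(matrix.samples)} samples, fewer than min_samples={min_samples}"
        )
    retained = []
    for name in matrix.allergens:
        identities = matrix.best_identity.loc[name].to_numpy(dtype=float)
        if np.isnan(identities).all():
            continue
        if not (np.nanmax(identities) > id_thresh):
            continue
        support = int((matrix.rel_abundance.loc[name] > abund_thresh).sum())
        if support >= min_samples:
            retained.append(name)
    return retained


def top_allergens(matrix: AllergenExpressionMatrix, k: int = 6) -> tuple[list[str], pd.Series]:
    """Allergens ordered by mean relative abundance, plus the per-sample
    cumulative share held by the top ``k``."""
    mean_rel = matrix.rel_abundance.mean(axis=1, skipna=True)
    order = mean_rel.sort_values(ascending=False, kind="stable").index.tolist()
    top = order[:k]
    cumulative = matrix.rel_abundance.loc[top].sum(axis=0)
    return order, cumulative


def cluster_fish(
    matrix: AllergenExpressionMatrix | pd.DataFrame,
    pv_name: str = "PV",
    k: int = 2,
) -> FishGrouping:
    """Cluster samples into PV-high/PV-low on profile correlation.

    Pairwise Pearson r between sample relative-abundance vectors gives a
    1 - r distance; average-linkage agglomeration is cut at ``k`` = 2 and
    the cluster with the higher mean parvalbumin relative abundance is
    labelled "PV-high".  Constant (zero-variance) profiles are excluded
    with a warning.
    """
    rel = matrix.rel_abundance if isinstance(matrix, AllergenExpressionMatrix) else matrix
    rel = rel.dropna(axis=1, how="all")
    excluded = [s for s in rel.columns if rel[s].std(ddof=0) == 0 or rel[s].isna().any()]
    if excluded:
        logger.warning("excluding constant/undefined profiles: %s", excluded)
    rel = rel.drop(columns=excluded)
    samples = list(rel.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 usable samples to cluster")
    if rel.shape[0] < 2:
        raise ValueError("need at least 2 allergens to correlate profiles")
    corr = rel.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    assignment = hierarchy.fcluster(linkage, t=k, criterion="maxclust")

    if pv_name in rel.index:
        pv = rel.loc[pv_name]
    else:
        logger.warning("allergen %r absent from matrix; PV-high label undefined", pv_name)
        pv = pd.Series(0.0, index=samples)
    means = {c: pv[np.array(samples)[assignment == c]].mean() for c in np.unique(assignment)}
    high_cluster = max(means, key=lambda c: (means[c], -c))
    labels = {
        s: ("PV-high" if c == high_cluster else "PV-low") for s, c in zip(samples, assignment)
    }
    return FishGrouping(labels=labels, correlation=corr, linkage=linkage, excluded=excluded)


def fish_means(table: pd.DataFrame, sep: str = "_") -> pd.DataFrame:
    """Average replicate sample columns ("cod_1", "cod_2" -> "cod").

    Replicates are identified by stripping the trailing ``sep``-delimited
    token when it is an integer.
    """
    groups: dict[str, list[str]] = {}
    for col in table.columns:
        head, _, tail = col.rpartition(sep)
        fish = head if head and tail.isdigit() else col
        groups.setdefault(fish, []).append(col)
    return pd.DataFrame({fish: table[cols].mean(axis=1) for fish, cols in groups.items()})
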