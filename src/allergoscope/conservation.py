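"""Family consensus and per-sequence conservation scores from a protein
multiple alignment.

The statistic: at each alignment column, every symbol (20 amino acids
plus the gap) gets a frequency with the number of sequences as the
denominator.  A sequence's conservation score is the mean, over the
columns where it carries a residue, of the frequency of *its own*
residue at that column.  A score of 1 means the sequence is identical
to the whole family at every position it occupies; rare residues and
residues falling in mostly-gapped columns pull the score down.  The
consensus string keeps, per column, the most frequent non-gap residue
and drops columns where gaps reach half the family.

Applied to parvalbumins this quantifies how representative one family
member (e.g. a commercial recombinant) is of the family as a whole —
a proxy for expected IgE cross-reactivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .scan import AlignmentParams, _aligner

GAP = "-"


@dataclass
class ConservationProfile:
    """Column residue frequencies, consensus, and per-sequence scores."""

    msa_ids: list[str]
    width: int
    column_freqs: list[dict[str, float]]
    consensus: str
    consensus_columns: list[int]  # 0-based retained column indices
    per_sequence_score: dict[str, float]


def column_frequencies(msa: list[SequenceRecord]) -> list[dict[str, float]]:
    """Per-column symbol frequencies; gaps count as a symbol.

    Requires an ungapped-width-consistent alignment of at least two
    sequences; frequencies at each column sum to 1.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(msa[0].seq)
    for rec in msa:
        if len(rec.seq) != width:
            raise ValueError(f"ragged alignment at record {rec.id!r}")
    n = len(msa)
    freqs: list[dict[str, float]] = []
    for col in range(width):
        counts: dict[str, int] = {}
        for rec in msa:
            ch = rec.seq[col]
            counts[ch] = counts.get(ch, 0) + 1
        freqs.append({ch: c / n for ch, c in counts.items()})
    return freqs


def build_consensus(column_freqs: list[dict[str, float]]) -> tuple[str, list[int]]:
    """Most frequent non-gap residue per column; gap-majority columns dropped.

    A column is dropped when the gap frequency is >= 0.5.  Residue ties
    break alphabetically.  Returns the consensus string and the 0-based
    indices of retained columns.
    """
    consensus: list[str] = []
    retained: list[int] = []
    for idx, freqs in enumerate(column_freqs):
        if freqs.get(GAP, 0.0) >= 0.5:
            continue
        residues = {ch: f for ch, f in freqs.items() if ch != GAP}
        best = min(residues.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        consensus.append(best)
        retained.append(idx)
    if not consensus:
        raise ValueError("all columns are gap-majority; consensus is empty")
    return "".join(consensus), retained


def conservation_score(
    record: SequenceRecord,
    column_freqs: list[dict[str, float]],
    columns: list[int] | None = None,
) -> float:
    """Average family frequency of the sequence's own residues.

    ``columns`` restricts scoring to the given 0-based column set
    (e.g. the consensus-retained frame); by default every column where
    the sequence has a non-gap residue is scored.
    """
    idx = range(len(column_freqs)) if columns is None else columns
    values = [
        column_freqs[i][record.seq[i]]
        for i in idx
        if record.seq[i] != GAP
    ]
    if not values:
        raise ValueError(f"sequence {record.id!r} has no residues in the scored columns")
    return float(np.mean(values))


def conservation_profile(
    msa: list[SequenceRecord], columns: str = "all"
) -> ConservationProfile:
    """Full profile: frequencies, consensus, and every sequence's score.

    ``columns`` is "all" (score each sequence over its own non-gap
    columns, the default) or "consensus" (restrict scoring to the
    consensus-retained columns).
    """
    if columns not in ("all", "consensus"):
        raise ValueError("columns must be 'all' or 'consensus'")
    freqs = column_frequencies(msa)
    consensus, retained = build_consensus(freqs)
    scored_columns = retained if columns == "consensus" else None
    scores = {rec.id: conservation_score(rec, freqs, scored_columns) for rec in msa}
    return ConservationProfile(
        msa_ids=[r.id for r in msa],
        width=len(freqs),
        column_freqs=freqs,
        consensus=consensus,
        consensus_columns=retained,
        per_sequence_score=scores,
    )


def pairwise_global_identity(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> float:
    """Percent identity under an end-to-end (global, affine-gap) alignment.

    Identity is identical columns over all alignment columns, including
    gap columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignmentParams()
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "global")
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * identical / len(a)


def profile_to_frames(profile: ConservationProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular views: per-sequence scores and per-column frequencies."""
    scores = pd.DataFrame(
        sorted(profile.per_sequence_score.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["sequence", "conservation_score"],
    )
    symbols = sorted({ch for col in profile.column_freqs for ch in col})
    freq_rows = [
        {"column": i + 1, **{ch: col.get(ch, 0.0) for ch in symbols}}
        for i, col in enumerate(profile.column_freqs)
    ]
    return scores, pd.DataFrame(freq_rows)
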