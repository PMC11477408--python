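"""Translated homology scan of assembled transcripts against an allergen
reference.

Each transcript is translated in all six reading frames and locally
aligned (Smith-Waterman, affine gaps, BLOSUM62 by default) against every
reference allergen protein.  For each transcript/allergen pair only the
best-scoring frame is kept; hits are filtered on pairwise identity
(>= 50% of alignment columns by default) and subject coverage (aligned
subject span strictly exceeding 90% of the reference length), and each
surviving transcript is assigned one primary allergen — its lowest
E-value hit.  Identity tiers (<70 low, 70-90 medium, >=90 high) annotate
each hit for allergen-probability triage.

E-values follow the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with
fixed gapped-BLOSUM62 constants; with m and n fixed per transcript this
ranks hits identically to the raw score, so absolute calibration is not
load-bearing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import AllergenRecord, SequenceRecord

FRAMES = (1, 2, 3, -1, -2, -3)

# Gapped BLOSUM62 Karlin-Altschul constants (natural-log units).
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap protein alignment parameters.

    A gap of length L is penalised ``gap_open + L * gap_extend``
    (protein-search convention: open 11, extend 1).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class ScanThresholds:
    """Identity/coverage filters and identity-tier boundaries (percent)."""

    min_identity_pct: float = 50.0
    min_subject_coverage_pct: float = 90.0
    tier_medium: float = 70.0
    tier_high: float = 90.0

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= self.tier_medium <= self.tier_high <= 100):
            raise ValueError(
                "need 0 < min_identity_pct <= tier_medium <= tier_high <= 100"
            )

    def tier(self, identity_pct: float) -> str:
        if identity_pct >= self.tier_high:
            return "high"
        if identity_pct >= self.tier_medium:
            return "medium"
        return "low"


@dataclass(frozen=True)
class LocalAlignment:
    """One optimal local alignment between two protein sequences."""

    score: float
    aligned_query: str
    aligned_subject: str
    query_span: tuple[int, int]  # 1-based closed interval on the query
    subject_span: tuple[int, int]  # 1-based closed interval on the subject
    n_columns: int
    n_identical: int


@dataclass
class AlignmentHit:
    """A filtered transcript-to-allergen local alignment."""

    transcript_id: str
    allergen_id: str
    allergen_name: str
    organism: str
    frame: int
    raw_score: float
    bit_score: float
    e_value: float
    identity_pct: float
    subject_coverage_pct: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    tier: str = "low"
    is_primary: bool = False


def six_frame_translate(nt_seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; stop codons are rendered '*' and retained;
    the trailing 1-2 bases that do not fill a codon are dropped in each
    frame.  Frames are keyed +1,+2,+3 (forward) and -1,-2,-3 (reverse
    complement, same offsets).
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) < 3:
        raise ValueError(f"sequence length {len(nt_seq)} < 3: nothing to translate")
    fwd = Seq(nt_seq)
    rev = fwd.reverse_complement()
    out: dict[int, str] = {}
    for frame in FRAMES:
        src = fwd if frame > 0 else rev
        offset = abs(frame) - 1
        sub = src[offset:]
        sub = sub[: len(sub) - (len(sub) % 3)]
        out[frame] = str(sub.translate(table=1))
    return out


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # PairwiseAligner's open_gap_score applies to the first gap position,
    # so open 11/extend 1 maps to scores -12 / -1.
    # this also sets the end-gap scores, so global mode is true
    # end-to-end alignment with end gaps penalised like internal ones
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_score(query_aa: str, subject_aa: str, params: AlignmentParams | None = None) -> float:
    """Optimal local-alignment score only (cheaper than the full traceback)."""
    params = params or AlignmentParams()
    if not query_aa or not subject_aa:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "local")
    return float(aligner.score(query_aa, subject_aa))


def local_align(query_aa: str, subject_aa: str, params: AlignmentParams | None = None) -> LocalAlignment | None:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns ``None`` when the optimal score is 0 (no positively scoring
    local alignment exists, hence no hit).
    """
    params = params or AlignmentParams()
    if not query_aa or not subject_aa:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "local")
    score = float(aligner.score(query_aa, subject_aa))
    if score <= 0:
        return None
    aln = aligner.align(query_aa, subject_aa)[0]
    aligned_q, aligned_s = str(aln[0]), str(aln[1])
    blocks_q, blocks_s = aln.aligned
    q_span = (int(blocks_q[0][0]) + 1, int(blocks_q[-1][1]))
    s_span = (int(blocks_s[0][0]) + 1, int(blocks_s[-1][1]))
    n_identical = sum(1 for a, b in zip(aligned_q, aligned_s) if a == b and a != "-")
    return LocalAlignment(
        score=score,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        query_span=q_span,
        subject_span=s_span,
        n_columns=len(aligned_q),
        n_identical=n_identical,
    )


def hit_metrics(alignment: LocalAlignment, subject_len: int, query_len: int, db_residues: int) -> tuple[float, float, float, float]:
    """Identity %, subject coverage %, bit score and E-value for a hit.

    Identity is identical columns over alignment columns; coverage is
    the aligned subject span over the subject length; the bit score and
    E-value use the Karlin-Altschul form with m = query length and
    n = total database residues.
    """
    identity_pct = 100.0 * alignment.n_identical / alignment.n_columns
    span = alignment.subject_span[1] - alignment.subject_span[0] + 1
    coverage_pct = 100.0 * span / subject_len
    bit_score = (KA_LAMBDA * alignment.score - math.log(KA_K)) / math.log(2)
    e_value = KA_K * query_len * db_residues * math.exp(-KA_LAMBDA * alignment.score)
    return identity_pct, coverage_pct, bit_score, e_value


@dataclass
class ScanResult:
    """All surviving hits plus the per-transcript primary assignment."""

    hits: list[AlignmentHit] = field(default_factory=list)
    primary: dict[str, str] = field(default_factory=dict)  # transcript -> allergen_id

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "transcript", "allergen", "allergen_name", "organism", "frame",
            "score", "bitscore", "evalue", "identity_pct", "subject_cov_pct",
            "tier", "primary_flag",
        ]
        rows = [
            {
                "transcript": h.transcript_id,
                "allergen": h.allergen_id,
                "allergen_name": h.allergen_name,
                "organism": h.organism,
                "frame": h.frame,
                "score": h.raw_score,
                "bitscore": round(h.bit_score, 4),
                "evalue": f"{h.e_value:.6g}",
                "identity_pct": round(h.identity_pct, 4),
                "subject_cov_pct": round(h.subject_coverage_pct, 4),
                "tier": h.tier,
                "primary_flag": int(h.is_primary),
            }
            for h in self.hits
        ]
        return pd.DataFrame(rows, columns=cols)


def scan_transcriptome(
    transcripts: list[SequenceRecord],
    allergen_db: list[AllergenRecord],
    thresholds: ScanThresholds | None = None,
    params: AlignmentParams | None = None,
) -> ScanResult:
    """Scan a transcript set against the allergen reference.

    For each (transcript, allergen) pair only the best-frame, best-score
    local alignment is retained; hits must pass the identity and
    subject-coverage thresholds.  Each surviving transcript is assigned
    a single primary allergen: the hit with the lowest E-value, ties
    broken by higher identity and then lexicographic allergen id.
    """
    if not allergen_db:
        raise ValueError("allergen database is empty")
    thresholds = thresholds or ScanThresholds()
    params = params or AlignmentParams()
    db_residues = sum(len(a.seq) for a in allergen_db)

    result = ScanResult()
    for transcript in transcripts:
        frames = six_frame_translate(transcript.seq)
        transcript_hits: list[AlignmentHit] = []
        for allergen in allergen_db:
            best_frame, best_score = None, 0.0
            for frame, aa in frames.items():
                if not aa:
                    continue
                score = local_align_score(aa, allergen.seq, params)
                if score > best_score:
                    best_frame, best_score = frame, score
            if best_frame is None:
                continue
            aln = local_align(frames[best_frame], allergen.seq, params)
            if aln is None:
                continue
            identity, coverage, bits, evalue = hit_metrics(
                aln, len(allergen.seq), len(frames[best_frame]), db_residues
            )
            if identity < thresholds.min_identity_pct:
                continue
            if coverage <= thresholds.min_subject_coverage_pct:
                continue
            transcript_hits.append(
                AlignmentHit(
                    transcript_id=transcript.id,
                    allergen_id=allergen.id,
                    allergen_name=allergen.name,
                    organism=allergen.organism,
                    frame=best_frame,
                    raw_score=aln.score,
                    bit_score=bits,
                    e_value=evalue,
                    identity_pct=identity,
                    subject_coverage_pct=coverage,
                    query_span=aln.query_span,
                    subject_span=aln.subject_span,
                    tier=thresholds.tier(identity),
                )
            )
        if transcript_hits:
            best = min(
                transcript_hits,
                key=lambda h: (h.e_value, -h.identity_pct, h.allergen_id),
            )
            best.is_primary = True
            result.primary[transcript.id] = best.allergen_id
        result.hits.extend(transcript_hits)
    return result


def hits_from_frame(table: pd.DataFrame) -> ScanResult:
    """Rebuild a ScanResult from a hits table written by :meth:`ScanResult.to_frame`."""
    result = ScanResult()
    for _, row in table.iterrows():
        hit = AlignmentHit(
            transcript_id=str(row["transcript"]),
            allergen_id=str(row["allergen"]),
            allergen_name=str(row["allergen_name"]),
            organism=str(row["organism"]),
            frame=int(row["frame"]),
            raw_score=float(row["score"]),
            bit_score=float(row["bitscore"]),
            e_value=float(row["evalue"]),
            identity_pct=float(row["identity_pct"]),
            subject_coverage_pct=float(row["subject_cov_pct"]),
            query_span=(0, 0),
            subject_span=(0, 0),
            tier=str(row["tier"]),
            is_primary=bool(int(row["primary_flag"])),
        )
        result.hits.append(hit)
        if hit.is_primary:
            result.primary[hit.transcript_id] = hit.allergen_id
    return result
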