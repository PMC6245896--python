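"""AMP candidate screening.

Two complementary filters, both gated at a significance threshold:

* a position-specific profile (PWM) scan of translated frames against a
  signal-peptide protein alignment, with empirical shuffle significance;
* a translated local-alignment search (Smith-Waterman, affine gaps,
  BLOSUM62) of contigs against a custom database of known AMP precursors,
  with Karlin-Altschul E-values.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .seqcore import NucSeq, PepSeq, translate_six_frames

__all__ = [
    "ProfileModel",
    "SearchHit",
    "build_profile",
    "profile_scan",
    "translated_search",
    "estimate_lambda",
    "write_hits_tsv",
]

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041

#: Robinson-Robinson background amino-acid frequencies.
BACKGROUND_FREQS = {
    "A": 0.0780, "C": 0.0192, "D": 0.0542, "E": 0.0629, "F": 0.0405,
    "G": 0.0738, "H": 0.0226, "I": 0.0514, "K": 0.0574, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0585, "V": 0.0644, "W": 0.0131, "Y": 0.0321,
}


@dataclass(frozen=True)
class SearchHit:
    """One alignment hit with BLAST-like summary statistics."""

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    identity: float  # percent, 0-100
    coverage: float  # percent of query spanned, 0-100
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    raw_score: float = 0.0
    matches: int = 0
    mismatches: int = 0
    gaps: int = 0
    aln_length: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError("identity out of range")
        if not 0 <= self.coverage <= 100:
            raise ValueError("coverage out of range")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific log-odds profile over the 20 residues.

    ``probs`` is (L, 20); each row sums to 1 before log-odds conversion.
    """

    probs: np.ndarray
    log_odds: np.ndarray
    pseudocount: float
    source_id: str

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.probs.argmax(axis=1))


def build_profile(
    alignment: list[PepSeq],
    pseudocount: float = 0.5,
    background: dict[str, float] | None = None,
    source_id: str = "profile",
    max_gap_frac: float = 0.5,
) -> ProfileModel:
    """Column frequencies with additive pseudocounts; log-odds vs background.

    Gapped protein sequences (with '-') of equal length; columns with more
    than ``max_gap_frac`` gaps are dropped.
    """
    if not alignment:
        raise ValueError("empty alignment")
    rows = [p.residues if isinstance(p, PepSeq) else str(p) for p in alignment]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows must have uniform length")
    if background is None:
        background = {a: 1.0 / 20 for a in AA_ORDER}
    bg = np.array([background[a] for a in AA_ORDER])
    ncols = len(rows[0])
    kept_cols = []
    for c in range(ncols):
        col = [r[c] for r in rows]
        if col.count("-") / len(col) > max_gap_frac:
            continue
        counts = np.full(20, pseudocount, dtype=float)
        for a in col:
            if a in _AA_INDEX:
                counts[_AA_INDEX[a]] += 1.0
        total = counts.sum()
        if total == 0:
            raise ValueError(f"column {c} has no countable residues")
        kept_cols.append(counts / total)
    probs = np.array(kept_cols)
    with np.errstate(divide="ignore"):
        log_odds = np.where(probs > 0, np.log2(np.maximum(probs, 1e-300) / bg), -np.inf)
    return ProfileModel(probs=probs, log_odds=log_odds, pseudocount=pseudocount,
                        source_id=source_id)


def _best_window_score(profile: ProfileModel, seq: str) -> float:
    """Best sum-of-log-odds over all ungapped placements of the profile."""
    L = profile.length
    lo = profile.log_odds
    if len(seq) < L:
        # score the full profile against the short sequence, left-aligned
        score = 0.0
        for i, a in enumerate(seq):
            if a in _AA_INDEX:
                v = lo[i, _AA_INDEX[a]]
                score += v if np.isfinite(v) else -10.0
        return score
    best = -math.inf
    idx = [_AA_INDEX.get(a, -1) for a in seq]
    for start in range(len(seq) - L + 1):
        score = 0.0
        for i in range(L):
            j = idx[start + i]
            if j >= 0:
                v = lo[i, j]
                score += v if np.isfinite(v) else -10.0
        if score > best:
            best = score
    return best


def profile_scan(
    profile: ProfileModel,
    peptides: list[PepSeq],
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[SearchHit]:
    """Empirical-significance profile scan.

    For each peptide: best-window profile score; significance = fraction of
    ``n_shuffles`` residue-shuffled versions scoring at least as high; retain
    peptides with significance < alpha.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles < 20 gives insufficient resolution for alpha=0.05")
    rng = random.Random(seed)
    hits = []
    for pep in peptides:
        seq = pep.sequence
        if not seq:
            continue
        observed = _best_window_score(profile, seq)
        chars = list(seq)
        exceed = 0
        for _ in range(n_shuffles):
            rng.shuffle(chars)
            if _best_window_score(profile, "".join(chars)) >= observed:
                exceed += 1
        pvalue = exceed / n_shuffles
        if pvalue < alpha:
            hits.append(
                SearchHit(
                    query_id=pep.id,
                    subject_id=profile.source_id,
                    bit_score=observed,
                    evalue=pvalue,
                    identity=0.0,
                    coverage=0.0,
                    query_range=(0, len(seq)),
                    subject_range=(0, profile.length),
                    raw_score=observed,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Translated search


def _local_aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: a gap of length k costs open + k*extend
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


def _alignment_stats(aln) -> tuple[int, int, int, int, tuple[int, int], tuple[int, int]]:
    """(matches, mismatches, gaps, columns, query span, subject span)."""
    q, s = aln[0], aln[1]
    matches = mismatches = gaps = 0
    for x, y in zip(q, s):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    qspan = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    sspan = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    return matches, mismatches, gaps, len(q), qspan, sspan


def estimate_lambda(
    matrix_name: str = "BLOSUM62",
    background: dict[str, float] | None = None,
) -> float:
    """Ungapped Karlin-Altschul lambda for a scoring matrix: the positive root
    of sum_ij p_i p_j exp(lambda * s_ij) = 1."""
    if background is None:
        background = BACKGROUND_FREQS
    mat = substitution_matrices.load(matrix_name)
    aas = [a for a in AA_ORDER]
    p = np.array([background[a] for a in aas])
    p = p / p.sum()
    s = np.array([[mat[a, b] for b in aas] for a in aas])

    def f(lam: float) -> float:
        return float(np.sum(np.outer(p, p) * np.exp(lam * s)) - 1.0)

    return brentq(f, 1e-6, 2.0)


def karlin_altschul_evalue(
    score: float, m: int, n: int,
    lam: float = BLOSUM62_GAPPED_LAMBDA, k: float = BLOSUM62_GAPPED_K,
) -> tuple[float, float]:
    """(E-value, bit score) for a raw local alignment score."""
    evalue = k * m * n * math.exp(-lam * score)
    bits = (lam * score - math.log(k)) / math.log(2)
    return evalue, bits


def translated_search(
    contigs: list[NucSeq],
    db: list[PepSeq],
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    alpha: float = 0.05,
    lam: float = BLOSUM62_GAPPED_LAMBDA,
    k: float = BLOSUM62_GAPPED_K,
) -> list[SearchHit]:
    """BLASTx-style screen: six-frame translate each contig, Smith-Waterman
    against every database entry, keep the best hit per contig with E < alpha.

    Best hit = lowest E-value, ties by higher identity then database order.
    """
    if not db:
        raise ValueError("empty database")
    aligner = _local_aligner(matrix_name, gap_open, gap_extend)
    db_size = sum(len(p.sequence) for p in db)
    hits = []
    for contig in contigs:
        if len(contig.bases) < 3:
            logger.info("contig %s shorter than one codon; skipped", contig.id)
            continue
        frames = translate_six_frames(contig)
        # search space spans every translated frame, not just the hit's frame
        m_total = sum(len(f.sequence) for f in frames)
        best: SearchHit | None = None
        for frame_pep in frames:
            qseq = frame_pep.sequence
            if not qseq:
                continue
            for subject in db:
                sseq = subject.sequence
                score = aligner.score(qseq, sseq)
                if score <= 0:
                    continue
                evalue, bits = karlin_altschul_evalue(score, m_total, db_size, lam, k)
                if best is not None and evalue > best.evalue:
                    continue
                aln = aligner.align(qseq, sseq)[0]
                matches, mism, gaps, cols, qspan, sspan = _alignment_stats(aln)
                identity = 100.0 * matches / cols if cols else 0.0
                coverage = 100.0 * (qspan[1] - qspan[0]) / len(qseq)
                hit = SearchHit(
                    query_id=contig.id,
                    subject_id=subject.id,
                    bit_score=bits,
                    evalue=evalue,
                    identity=identity,
                    coverage=coverage,
                    query_range=qspan,
                    subject_range=sspan,
                    raw_score=score,
                    matches=matches,
                    mismatches=mism,
                    gaps=gaps,
                    aln_length=cols,
                )
                if best is None or (hit.evalue, -hit.identity) < (best.evalue, -best.identity):
                    best = hit
        if best is not None and best.evalue < alpha:
            hits.append(best)
    return hits


def protein_search(
    query: PepSeq,
    db: list[PepSeq],
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    lam: float = BLOSUM62_GAPPED_LAMBDA,
    k: float = BLOSUM62_GAPPED_K,
) -> list[SearchHit]:
    """BLASTp-style search of one peptide against the database.

    Returns all positive-scoring hits sorted by (E-value, -identity,
    database order); no significance gate is applied here so callers can
    choose their own alpha.
    """
    if not db:
        raise ValueError("empty database")
    aligner = _local_aligner(matrix_name, gap_open, gap_extend)
    db_size = sum(len(p.sequence) for p in db)
    qseq = query.sequence
    hits = []
    for order, subject in enumerate(db):
        score = aligner.score(qseq, subject.sequence)
        if score <= 0:
            continue
        evalue, bits = karlin_altschul_evalue(score, len(qseq), db_size, lam, k)
        aln = aligner.align(qseq, subject.sequence)[0]
        matches, mism, gaps, cols, qspan, sspan = _alignment_stats(aln)
        hits.append(
            (
                order,
                SearchHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    bit_score=bits,
                    evalue=evalue,
                    identity=100.0 * matches / cols if cols else 0.0,
                    coverage=100.0 * (qspan[1] - qspan[0]) / len(qseq),
                    query_range=qspan,
                    subject_range=sspan,
                    raw_score=score,
                    matches=matches,
                    mismatches=mism,
                    gaps=gaps,
                    aln_length=cols,
                ),
            )
        )
    hits.sort(key=lambda oh: (oh[1].evalue, -oh[1].identity, oh[0]))
    return [h for _, h in hits]


def write_hits_tsv(path, hits: list[SearchHit]) -> None:
    """Write hits in the conventional 12-column tab-separated format."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, f"{h.identity:.1f}", h.aln_length,
                        h.mismatches, h.gaps, h.query_range[0] + 1, h.query_range[1],
                        h.subject_range[0] + 1, h.subject_range[1],
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
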