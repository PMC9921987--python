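"""All-vs-all alignment of cluster representatives.

The merge step only needs, for every ordered pair of representatives, a
directed local-alignment hit with an e-value and a query coverage.  Two
backends provide that table:

* the internal backend: exhaustive affine-gap Smith-Waterman (BLOSUM62,
  gap open 11 / extend 1 — the classic blastp defaults) with a shared
  k-mer prefilter and Karlin-Altschul e-values;
* an external backend: any search tool's 12-column BLAST tabular output,
  re-filtered against the same e-value and coverage thresholds so the
  downstream merge behaves identically regardless of backend.

E-values from the two backends are never compared numerically — each tool
models its search space differently — only through the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from completplus.errors import CompletPlusError, UnknownIdError
from completplus.io_formats import AlignmentHit, SequenceRecord, read_m8

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 /
#: extend 1 (the standard blastp combination).
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041

# The BLOSUM62 matrix alphabet lacks selenocysteine and pyrrolysine;
# score them as their closest standard residues.
_SCORING_TRANSLATION = str.maketrans({"U": "C", "O": "K"})


@dataclass
class SearchParams:
    """Tunable parameters of the all-vs-all representative search.

    ``evalue_threshold`` (default 0.001) and ``min_query_coverage``
    (default 0.8) gate which directed hits survive; they are applied
    identically to internal and external hits.  ``min_kmer_matches = 0``
    disables the prefilter (every pair is aligned).
    ``effective_db_letters`` is the n in the e-value formula
    ``E = m * n * 2**(-bitscore)``; ``"auto"`` means the summed length of
    the target set.  ``external_sensitivity`` is recorded for provenance
    and passed through to external search tools only — the internal
    backend is exhaustive and has no sensitivity knob.
    """

    evalue_threshold: float = 0.001
    min_query_coverage: float = 0.8
    gap_open: int = 11
    gap_extend: int = 1
    kmer_size: int = 3
    min_kmer_matches: int = 1
    effective_db_letters: int | str = "auto"
    external_sensitivity: float = 7.5

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if not 0.0 <= self.min_query_coverage <= 1.0:
            raise ValueError("min_query_coverage must be in [0, 1]")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.min_kmer_matches < 0:
            raise ValueError("min_kmer_matches must be >= 0")


@dataclass
class ScoringScheme:
    """Substitution matrix plus the Karlin-Altschul (lambda, K) pair that
    converts raw Smith-Waterman scores to bit scores:
    ``bitscore = (lambda * S - ln K) / ln 2``."""

    matrix: object = None
    lam: float = BLOSUM62_GAPPED_LAMBDA
    K: float = BLOSUM62_GAPPED_K

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = substitution_matrices.load("BLOSUM62")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


def _make_aligner(scheme: ScoringScheme, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # Biopython charges open_gap_score for the first gap position; the
    # blastp convention charges open + extend for a length-1 gap.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _scoring_residues(record: SequenceRecord) -> str:
    return record.residues.translate(_SCORING_TRANSLATION)


def evalue_from_bitscore(bitscore: float, query_length: int, db_letters: int) -> float:
    return query_length * db_letters * 2.0 ** (-bitscore)


def smith_waterman(
    query: SequenceRecord,
    target: SequenceRecord,
    scheme: ScoringScheme | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    effective_db_letters: int | None = None,
) -> AlignmentHit | None:
    """Optimal affine-gap local alignment of ``query`` against ``target``.

    Returns ``None`` when the optimal local score is 0 (no positive-scoring
    path).  Coordinates are 1-based inclusive; ``pct_identity`` is
    identities over alignment columns; the e-value uses
    ``m = len(query)`` and ``n = effective_db_letters`` (defaulting to
    ``len(target)`` for a single-target search).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if len(query) == 0 or len(target) == 0:
        raise CompletPlusError("cannot align an empty sequence")
    aligner = _make_aligner(scheme, gap_open, gap_extend)
    q, t = _scoring_residues(query), _scoring_residues(target)
    score = aligner.score(q, t)
    if score <= 0:
        return None
    aln = aligner.align(q, t)[0]
    return _hit_from_alignment(
        aln, score, query, target, scheme,
        effective_db_letters if effective_db_letters is not None else len(target),
    )


def _hit_from_alignment(aln, score, query, target, scheme, db_letters) -> AlignmentHit:
    counts = aln.counts()
    q_blocks, t_blocks = aln.aligned  # first sequence passed = query
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    t_start, t_end = int(t_blocks[0][0]) + 1, int(t_blocks[-1][1])
    gap_openings = int(counts.open_internal_insertions) + int(
        counts.open_internal_deletions
    )
    aln_length = int(aln.length)
    bits = scheme.bitscore(score)
    return AlignmentHit(
        query_id=query.id,
        target_id=target.id,
        pct_identity=100.0 * counts.identities / aln_length,
        aln_length=aln_length,
        mismatches=int(counts.mismatches),
        gap_openings=gap_openings,
        q_start=q_start,
        q_end=q_end,
        t_start=t_start,
        t_end=t_end,
        evalue=evalue_from_bitscore(bits, len(query), db_letters),
        bitscore=bits,
        query_coverage=(q_end - q_start + 1) / len(query),
        raw_score=float(score),
    )


def _kmer_set(residues: str, k: int) -> set[str]:
    return {residues[i : i + k] for i in range(len(residues) - k + 1)}


def _passes(hit: AlignmentHit, params: SearchParams) -> bool:
    return (
        hit.evalue <= params.evalue_threshold
        and hit.query_coverage >= params.min_query_coverage
    )


def _swap_hit(hit: AlignmentHit, query: SequenceRecord, scheme: ScoringScheme,
              db_letters: int) -> AlignmentHit:
    """The reverse direction of a computed hit: the alignment itself is
    symmetric (symmetric matrix, symmetric gap costs), only the coordinate
    roles and the e-value's query length m change."""
    bits = hit.bitscore
    return AlignmentHit(
        query_id=hit.target_id,
        target_id=hit.query_id,
        pct_identity=hit.pct_identity,
        aln_length=hit.aln_length,
        mismatches=hit.mismatches,
        gap_openings=hit.gap_openings,
        q_start=hit.t_start,
        q_end=hit.t_end,
        t_start=hit.q_start,
        t_end=hit.q_end,
        evalue=evalue_from_bitscore(bits, len(query), db_letters),
        bitscore=bits,
        query_coverage=(hit.t_end - hit.t_start + 1) / len(query),
        raw_score=hit.raw_score,
    )


def all_vs_all(
    reps: Sequence[SequenceRecord],
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
) -> list[AlignmentHit]:
    """Directed hits for every ordered representative pair (self included).

    A hit q->t is emitted iff the k-mer prefilter passes (>=
    ``min_kmer_matches`` shared k-mers; self pairs always pass), the local
    alignment has positive score, ``evalue <= evalue_threshold`` and
    ``query_coverage >= min_query_coverage``.  Each unordered pair is
    aligned once and mirrored — the scoring is symmetric, so only e-value
    (through the query length m) differs between the two directions.
    The output order (pair-major, forward then reverse) is deterministic.
    """
    if params is None:
        params = SearchParams()
    if scheme is None:
        scheme = ScoringScheme()
    if len(reps) == 0:
        raise CompletPlusError("all_vs_all requires at least one representative")
    ids = [r.id for r in reps]
    if len(set(ids)) != len(ids):
        raise CompletPlusError("duplicate representative ids in search input")
    if params.effective_db_letters == "auto":
        db_letters = sum(len(r) for r in reps)
    else:
        db_letters = int(params.effective_db_letters)
    aligner = _make_aligner(scheme, params.gap_open, params.gap_extend)
    scoring = [_scoring_residues(r) for r in reps]
    kmers = (
        [_kmer_set(s, params.kmer_size) for s in scoring]
        if params.min_kmer_matches > 0
        else None
    )
    hits: list[AlignmentHit] = []
    for i, query in enumerate(reps):
        for j in range(i, len(reps)):
            target = reps[j]
            if kmers is not None and i != j:
                if len(kmers[i] & kmers[j]) < params.min_kmer_matches:
                    continue
            score = aligner.score(scoring[i], scoring[j])
            if score <= 0:
                continue
            aln = aligner.align(scoring[i], scoring[j])[0]
            fwd = _hit_from_alignment(aln, score, query, target, scheme, db_letters)
            if _passes(fwd, params):
                hits.append(fwd)
            if i != j:
                rev = _swap_hit(fwd, target, scheme, db_letters)
                if _passes(rev, params):
                    hits.append(rev)
    return hits


def load_external_hits(
    path,
    reps: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """Load an external tool's m8 file and re-filter it.

    Hits are re-checked against ``evalue_threshold`` and
    ``min_query_coverage`` so the merge behaves identically whichever
    backend produced the table.  A hit naming an id not among the
    representatives is an error.
    """
    if params is None:
        params = SearchParams()
    lengths = {r.id: len(r) for r in reps}
    hits = read_m8(path, lengths)
    for h in hits:
        if h.target_id not in lengths:
            raise UnknownIdError(f"alignment hit references unknown id {h.target_id!r}")
    return [h for h in hits if _passes(h, params)]
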