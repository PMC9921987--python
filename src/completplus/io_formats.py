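"""Readers/writers for every file format the tool touches.

Formats:

* FASTA (protein): the representative sequences (or the full input set).
* Cluster TSV: two tab-separated columns ``representative_id<TAB>member_id``
  — the dialect produced by MMseqs2 ``createtsv``, but tool-agnostic.
* BLAST tabular ("m8"): 12-column alignment interchange format
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore), 1-based inclusive coordinates.
* Relabeled TSV: the three-column output
  ``old_cluster_id<TAB>sequence_id<TAB>new_cluster_id``, one row per input
  sequence in input order.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from completplus.errors import ClusteringError, FormatError, UnknownIdError

# 20 standard amino acids plus the ambiguity/extension codes accepted on
# input (B=Asx, Z=Glx, X=any, U=Sec, O=Pyl, *=stop/terminator).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUO*")


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence.

    ``id`` is a whitespace-free token (for FASTA input, the header up to the
    first whitespace); ``residues`` are stored upper-case.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}: empty or contains whitespace")
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise FormatError(f"sequence {self.id!r} has zero residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Clustering:
    """A partition of sequence ids into clusters keyed by representative id.

    ``assignments`` is the ordered list of ``(representative_id, member_id)``
    pairs exactly as read; the order is preserved because it defines the
    traversal/output order downstream.  Every member appears exactly once.
    A representative that never lists itself as a member is tolerated but
    flagged with a warning and injected as a member of its own cluster (the
    merge step must be able to assign every representative).
    """

    assignments: list[tuple[str, str]]
    member_to_rep: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rep, member in self.assignments:
            if member in seen:
                if seen[member] != rep:
                    raise ClusteringError(
                        f"member {member!r} listed under two representatives "
                        f"({seen[member]!r} and {rep!r}): not a partition"
                    )
                raise ClusteringError(f"member {member!r} listed twice under {rep!r}")
            seen[member] = rep
        # Representatives must be members of their own cluster.
        reps = self.representatives_from(self.assignments)
        misplaced = [r for r in reps if r in seen and seen[r] != r]
        if misplaced:
            raise ClusteringError(
                f"representative(s) {misplaced} appear as members of a "
                "different cluster: not a partition"
            )
        missing = [r for r in reps if r not in seen]
        if missing:
            warnings.warn(
                f"representative(s) {missing} are not members of their own "
                "cluster; injecting self-membership",
                stacklevel=2,
            )
            missing_set = set(missing)
            fixed: list[tuple[str, str]] = []
            injected: set[str] = set()
            for rep, member in self.assignments:
                if rep in missing_set and rep not in injected:
                    fixed.append((rep, rep))
                    injected.add(rep)
                fixed.append((rep, member))
            self.assignments = fixed
            seen = {m: r for r, m in fixed}
        self.member_to_rep = seen

    @staticmethod
    def representatives_from(pairs: Sequence[tuple[str, str]]) -> list[str]:
        out, seen = [], set()
        for rep, _ in pairs:
            if rep not in seen:
                seen.add(rep)
                out.append(rep)
        return out

    @property
    def representatives(self) -> list[str]:
        """Representative ids in order of first appearance."""
        return self.representatives_from(self.assignments)

    def clusters(self) -> dict[str, list[str]]:
        """Mapping representative -> members, preserving order."""
        out: dict[str, list[str]] = {}
        for rep, member in self.assignments:
            out.setdefault(rep, []).append(member)
        return out

    def n_clusters(self) -> int:
        return len(self.representatives)

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class AlignmentHit:
    """One directed query->target local alignment result.

    Coordinates are 1-based inclusive (BLAST tabular convention);
    ``pct_identity`` is in [0, 100]; ``query_coverage`` is the aligned query
    span divided by the query length, in [0, 1].  ``raw_score`` is the raw
    Smith-Waterman score when the hit came from the internal aligner; it is
    not part of the m8 interchange format and is excluded from equality.
    """

    query_id: str
    target_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    evalue: float
    bitscore: float
    query_coverage: float
    raw_score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.t_start > self.t_end:
            raise FormatError(
                f"hit {self.query_id}->{self.target_id}: start > end "
                "(protein local alignment has no strand)"
            )
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}->{self.target_id}: negative e-value")
        if not 0.0 <= self.query_coverage <= 1.0 + 1e-12:
            raise FormatError(
                f"hit {self.query_id}->{self.target_id}: query_coverage "
                f"{self.query_coverage} outside [0, 1]"
            )


@dataclass(frozen=True)
class RelabeledRow:
    """One row of the three-column output: old label, sequence, new label."""

    old_cluster_id: str
    sequence_id: str
    new_cluster_id: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    The record id is the header token up to the first whitespace.  Records
    are returned in file order with residues upper-cased.  Duplicate ids,
    zero-length sequences, and an empty file are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise FormatError(f"FASTA record {rec.id!r} in {path} has an empty sequence")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"FASTA file {path} contains no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA (60-column wrapped)."""
    bio = (_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Cluster TSV

_HEADER_WORDS = ("cluster", "representative", "sequence", "member", "id", "rep")


def _looks_like_header(tokens: Sequence[str]) -> bool:
    low = [t.lower() for t in tokens]
    return all(any(w in t for w in _HEADER_WORDS) for t in low)


def read_cluster_tsv(
    path: str | os.PathLike, *, swap_columns: bool = False
) -> Clustering:
    """Read a two-column cluster TSV (representative, member) into a
    :class:`Clustering`.

    The MMseqs2 ``createtsv`` dialect puts the representative first; pass
    ``swap_columns=True`` for tools that emit (member, representative).
    Files are headerless by convention; a first line whose two tokens both
    look like column names (contain "cluster", "id", ...) is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cluster TSV not found: {path}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(tokens)}"
                )
            if lineno == 1 and _looks_like_header(tokens):
                continue
            rep, member = tokens
            if swap_columns:
                rep, member = member, rep
            pairs.append((rep, member))
    if not pairs:
        raise FormatError(f"cluster TSV {path} is empty")
    return Clustering(pairs)


def write_cluster_tsv(clustering: Clustering, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rep, member in clustering.assignments:
            fh.write(f"{rep}\t{member}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (m8)

_M8_COLUMNS = 12


def read_m8(
    path: str | os.PathLike, query_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Read a 12-column BLAST tabular file.

    ``query_lengths`` maps query id -> sequence length and is used to derive
    ``query_coverage = (q_end - q_start + 1) / query_length``; a hit whose
    query id is absent from the mapping is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"alignment file not found: {path}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != _M8_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_M8_COLUMNS} columns, got {len(tokens)}"
                )
            try:
                (qid, tid, pident, alen, mism, gapo,
                 qs, qe, ts, te, ev, bits) = tokens
                pident = float(pident)
                alen, mism, gapo = int(alen), int(mism), int(gapo)
                qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
                ev, bits = float(ev), float(bits)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable numeric field ({exc})")
            if qid not in query_lengths:
                raise UnknownIdError(
                    f"{path}:{lineno}: unknown query id {qid!r} "
                    "(no length available for coverage)"
                )
            cov = (qe - qs + 1) / query_lengths[qid]
            hits.append(
                AlignmentHit(qid, tid, pident, alen, mism, gapo,
                             qs, qe, ts, te, ev, bits, cov)
            )
    return hits


def write_m8(hits: Iterable[AlignmentHit], path: str | os.PathLike) -> None:
    """Write hits as 12-column BLAST tabular.

    Floats are written with ``repr`` (shortest exact representation) so that
    write-then-read round-trips reproduce the hits bit-for-bit; external
    tools that round their output are still read correctly.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.target_id, repr(h.pct_identity),
                        str(h.aln_length), str(h.mismatches), str(h.gap_openings),
                        str(h.q_start), str(h.q_end), str(h.t_start), str(h.t_end),
                        repr(h.evalue), repr(h.bitscore),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Relabeled three-column output


def write_relabeled_tsv(
    rows: Iterable[RelabeledRow],
    path: str | os.PathLike,
    *,
    header: bool = False,
) -> None:
    """Write the three-column (old, sequence, new) output table.

    Headerless by default; ``header=True`` prepends the column names."""
    with open(path, "w") as fh:
        if header:
            fh.write("old_cluster_id\tsequence_id\tnew_cluster_id\n")
        for row in rows:
            fh.write(f"{row.old_cluster_id}\t{row.sequence_id}\t{row.new_cluster_id}\n")


def read_relabeled_tsv(path: str | os.PathLike) -> list[RelabeledRow]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"relabeled TSV not found: {path}")
    rows: list[RelabeledRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(tokens)}"
                )
            if lineno == 1 and _looks_like_header(tokens):
                continue
            rows.append(RelabeledRow(*tokens))
    return rows
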