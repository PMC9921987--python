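"""Synthetic protein-family fixtures with known ground truth.

Real benchmarks for cluster merging are curated homology hierarchies
(families grouped into superfamilies) over hundreds of thousands of
sequences.  This module emulates their essential structure at desk scale:

* each family descends from a random ancestor sequence; members are
  derived by point substitutions at a controlled per-site rate, with
  substitution targets drawn from BLOSUM62-conditional probabilities
  (so that divergent homologs still score well under BLOSUM62), plus
  rare indels;
* families can optionally be grouped under shared superfamily ancestors
  at higher divergence, giving a two-level ground truth;
* a greedy incremental baseline clusterer (longest sequence becomes a
  representative, CD-HIT style) produces realistically over-split
  clusterings of those families;
* a batch partitioner splits a dataset for incremental-clustering
  experiments.

All randomness flows from the single seed in :class:`FamilySpec` (or the
explicit seed argument) through one named numpy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from Bio.Align import substitution_matrices

from completplus.errors import CompletPlusError
from completplus.io_formats import Clustering, SequenceRecord
from completplus.pairwise_search import ScoringScheme, _make_aligner, _scoring_residues

#: Canonical amino-acid order used by the generator.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff), in
#: AMINO_ACIDS order, normalized to sum to 1.
BLOSUM62_BACKGROUND = np.array(
    [0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068,
     0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073]
)
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()


def conditional_substitution_matrix() -> np.ndarray:
    """Row-stochastic matrix P(b | a) of substitution targets.

    Derived from the BLOSUM62 log-odds scores s_ab (half-bit units) and the
    background frequencies p: the implied target frequencies are
    q_ab ∝ p_a p_b 2^(s_ab/2); each row is normalized.  The diagonal is
    substantial, so a "substitution event" frequently resamples the same
    residue — the observed divergence is lower than the event rate.
    """
    m = substitution_matrices.load("BLOSUM62")
    s = np.array(
        [[m[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=np.float64
    )
    q = np.outer(BLOSUM62_BACKGROUND, BLOSUM62_BACKGROUND) * 2.0 ** (s / 2.0)
    return q / q.sum(axis=1, keepdims=True)


_COND = conditional_substitution_matrix()
_COND_CUM = np.cumsum(_COND, axis=1)


def expected_identity_to_ancestor(divergence: float,
                                  composition: np.ndarray | None = None) -> float:
    """Closed-form expected per-site identity between a member and its
    ancestor under the substitution-only model: 1 - d * (1 - p_same),
    where p_same is the composition-weighted diagonal of P(b | a)."""
    w = BLOSUM62_BACKGROUND if composition is None else composition
    p_same = float(np.dot(w, np.diag(_COND)))
    return 1.0 - divergence * (1.0 - p_same)


@dataclass
class FamilySpec:
    """Parameters of a synthetic family dataset.

    ``within_family_divergence`` is the expected substitution events per
    site between a member and its family ancestor (in [0, 1)); the default
    0.25 leaves members ~80% identical to the ancestor and ~65% identical
    to each other — far enough apart that a 90%-identity greedy clusterer
    over-splits the family, close enough that alignments remain highly
    significant.  ``indel_rate`` is expected indel events per site.
    Superfamilies, when requested, share a deeper ancestor from which
    family ancestors diverge at ``superfamily_divergence``.
    """

    n_families: int = 20
    seqs_per_family: int = 6
    seq_length: int = 110
    within_family_divergence: float = 0.25
    indel_rate: float = 0.01
    families_per_superfamily: int | None = None
    superfamily_divergence: float = 0.45
    alphabet_frequencies: np.ndarray = field(
        default_factory=lambda: BLOSUM62_BACKGROUND.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.seqs_per_family < 1 or self.seq_length < 1:
            raise CompletPlusError("family counts and lengths must be positive")
        if not 0.0 <= self.within_family_divergence < 1.0:
            raise CompletPlusError("within_family_divergence must be in [0, 1)")
        if self.indel_rate < 0:
            raise CompletPlusError("indel_rate must be >= 0")
        freqs = np.asarray(self.alphabet_frequencies, dtype=np.float64)
        if freqs.shape != (20,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise CompletPlusError("alphabet_frequencies must be a 20-vector summing to 1")
        self.alphabet_frequencies = freqs


@dataclass
class LabeledDataset:
    """Sequences plus their ground-truth family (and optional superfamily)
    labels; ``ancestors`` keeps each family's ancestral sequence for
    model-level checks."""

    sequences: list[SequenceRecord]
    truth: dict[str, str]                       # sequence id -> family
    superfamily: dict[str, str] | None = None   # family -> superfamily
    ancestors: dict[str, str] = field(default_factory=dict)

    def truth_labels(self, ids: list[str] | None = None) -> list[str]:
        ids = ids if ids is not None else [s.id for s in self.sequences]
        return [self.truth[i] for i in ids]

    def superfamily_labels(self, ids: list[str] | None = None) -> list[str]:
        if self.superfamily is None:
            raise CompletPlusError("dataset has no superfamily grouping")
        ids = ids if ids is not None else [s.id for s in self.sequences]
        return [self.superfamily[self.truth[i]] for i in ids]


def _substitute(indices: np.ndarray, divergence: float,
                rng: np.random.Generator) -> np.ndarray:
    """Apply substitution events at the given per-site rate; targets are
    drawn from the BLOSUM62-conditional distribution of the current residue
    (the diagonal is allowed, so some events are silent)."""
    out = indices.copy()
    mask = rng.random(out.size) < divergence
    k = int(mask.sum())
    if k:
        u = rng.random(k)
        rows = _COND_CUM[out[mask]]
        out[mask] = (u[:, None] >= rows).sum(axis=1)
    return out


def _apply_indels(indices: np.ndarray, indel_rate: float, freqs: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    if indel_rate <= 0:
        return indices
    positions = np.nonzero(rng.random(indices.size) < indel_rate)[0]
    seq = indices
    for pos in positions[::-1]:  # right-to-left keeps earlier positions valid
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            insert = rng.choice(20, size=length, p=freqs)
            seq = np.concatenate([seq[:pos], insert, seq[pos:]])
        else:
            seq = np.concatenate([seq[:pos], seq[pos + length:]])
    if seq.size == 0:  # never delete a sequence away entirely
        seq = rng.choice(20, size=1, p=freqs)
    return seq


def _to_str(indices: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in indices)


def generate_families(spec: FamilySpec) -> LabeledDataset:
    """Generate a labeled dataset of synthetic protein families.

    Deterministic given ``spec.seed``.  With
    ``families_per_superfamily`` set, family ancestors are themselves
    derived from shared superfamily ancestors at
    ``superfamily_divergence``, yielding a two-level ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.alphabet_frequencies
    n_fam = spec.n_families
    fam_names = [f"F{i:03d}" for i in range(n_fam)]
    superfamily: dict[str, str] | None = None
    fam_ancestors: list[np.ndarray] = []
    if spec.families_per_superfamily:
        per = spec.families_per_superfamily
        n_super = -(-n_fam // per)
        superfamily = {}
        for s in range(n_super):
            sf_anc = rng.choice(20, size=spec.seq_length, p=freqs)
            for f in range(s * per, min((s + 1) * per, n_fam)):
                fam_ancestors.append(
                    _substitute(sf_anc, spec.superfamily_divergence, rng)
                )
                superfamily[fam_names[f]] = f"SF{s:02d}"
    else:
        for _ in range(n_fam):
            fam_ancestors.append(rng.choice(20, size=spec.seq_length, p=freqs))
    sequences: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    for fam, anc in zip(fam_names, fam_ancestors):
        ancestors[fam] = _to_str(anc)
        for k in range(spec.seqs_per_family):
            member = _substitute(anc, spec.within_family_divergence, rng)
            member = _apply_indels(member, spec.indel_rate, freqs, rng)
            sid = f"{fam}_S{k:02d}"
            sequences.append(SequenceRecord(sid, _to_str(member)))
            truth[sid] = fam
    return LabeledDataset(sequences, truth, superfamily, ancestors)


def baseline_greedy_cluster(
    dataset: LabeledDataset,
    identity_threshold: float = 0.9,
    coverage_threshold: float = 0.8,
    scheme: ScoringScheme | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Clustering:
    """Greedy incremental clustering in the CD-HIT/linclust style.

    Sequences are visited by decreasing length (ties by input order); each
    joins the first existing representative it matches with alignment
    identity >= ``identity_threshold`` (identities over alignment columns)
    and query coverage >= ``coverage_threshold``, else it founds a new
    cluster.  With a high identity threshold this deliberately over-splits
    diverged families — the input condition the merge step repairs.
    """
    if not dataset.sequences:
        raise CompletPlusError("empty dataset")
    if scheme is None:
        scheme = ScoringScheme()
    aligner = _make_aligner(scheme, gap_open, gap_extend)
    order = sorted(
        range(len(dataset.sequences)),
        key=lambda i: (-len(dataset.sequences[i]), i),
    )
    rep_records: list[SequenceRecord] = []
    rep_scoring: list[str] = []
    pairs: list[tuple[str, str]] = []
    for idx in order:
        seq = dataset.sequences[idx]
        s = _scoring_residues(seq)
        assigned = None
        for rep, rs in zip(rep_records, rep_scoring):
            if aligner.score(s, rs) <= 0:
                continue
            aln = aligner.align(s, rs)[0]
            counts = aln.counts()
            identity = counts.identities / aln.length
            q_blocks = aln.aligned[0]
            span = int(q_blocks[-1][1]) - int(q_blocks[0][0])
            if identity >= identity_threshold and span / len(seq) >= coverage_threshold:
                assigned = rep
                break
        if assigned is None:
            rep_records.append(seq)
            rep_scoring.append(s)
            assigned = seq
        pairs.append((assigned.id, seq.id))
    # Emit representative-grouped pairs in representative creation order,
    # self-membership first (the createtsv convention).
    grouped: dict[str, list[str]] = {r.id: [] for r in rep_records}
    for rep_id, member_id in pairs:
        grouped[rep_id].append(member_id)
    ordered: list[tuple[str, str]] = []
    for rep in rep_records:
        members = grouped[rep.id]
        members.remove(rep.id)
        ordered.append((rep.id, rep.id))
        ordered.extend((rep.id, m) for m in members)
    return Clustering(ordered)


def partition_batches(
    dataset: LabeledDataset,
    n_batches: int,
    mode: Literal["by_class", "random"] = "by_class",
    seed: int = 0,
) -> list[LabeledDataset]:
    """Split a dataset into disjoint, exhaustive batches.

    ``by_class``: families are shuffled and split into nearly equal groups;
    each batch holds all sequences of its families (new classes per batch).
    ``random``: sequences are shuffled and split into nearly equal batches
    regardless of family.
    """
    if n_batches < 2:
        raise CompletPlusError("need at least 2 batches")
    rng = np.random.default_rng(seed)
    if mode == "by_class":
        families = sorted({dataset.truth[s.id] for s in dataset.sequences})
        if n_batches > len(families):
            raise CompletPlusError(
                f"cannot split {len(families)} families into {n_batches} batches"
            )
        families = list(np.array(families, dtype=object)[rng.permutation(len(families))])
        groups = [set(chunk) for chunk in np.array_split(np.array(families, dtype=object), n_batches)]
        batches_idx = [
            [i for i, s in enumerate(dataset.sequences)
             if dataset.truth[s.id] in g]
            for g in groups
        ]
    elif mode == "random":
        perm = rng.permutation(len(dataset.sequences))
        batches_idx = [list(chunk) for chunk in np.array_split(perm, n_batches)]
    else:
        raise CompletPlusError(f"unknown batch mode {mode!r}")
    out = []
    for idx in batches_idx:
        seqs = [dataset.sequences[i] for i in idx]
        fams = {dataset.truth[s.id] for s in seqs}
        out.append(
            LabeledDataset(
                sequences=seqs,
                truth={s.id: dataset.truth[s.id] for s in seqs},
                superfamily=(
                    {f: dataset.superfamily[f] for f in fams}
                    if dataset.superfamily is not None
                    else None
                ),
                ancestors={f: dataset.ancestors[f] for f in fams if f in dataset.ancestors},
            )
        )
    return out
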