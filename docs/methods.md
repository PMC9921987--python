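# Methods

## The merge procedure

Input: a FASTA file containing (at least) the representative sequences of
an existing clustering, and the clustering itself as ordered
`(representative_id, member_id)` pairs. The pipeline is

1. **Representative extraction** — keep exactly the sequences named in the
   clustering's first column, in clustering order. Extra sequences in the
   FASTA are ignored; a representative without a sequence is an error.
2. **All-vs-all search** — a directed hit `q→t` for every ordered pair of
   representatives (self included) that survives the filters
   (§ Search backends).
3. **Reciprocal filtering** — hits are sorted by ascending e-value
   (ties: descending bitscore, then lexicographic `(query, target)` —
   purely for determinism), self-hits are removed, and an undirected edge
   `{a, b}` is created iff the hits `a→b` *and* `b→a` both pass
   `evalue ≤ 0.001`. Reciprocity is mutual *presence* under the
   threshold, never mutual-best: a representative typically carries
   several reciprocal edges, and all of them are used.
4. **Component merge** — connected components of the reciprocal graph are
   merged. Each component is labeled by its *seed*: the member that
   appears first in the e-value-sorted reciprocal hit list (clustering
   order for isolated nodes, which keep their own label). Every sequence
   is then relabeled through the resulting old→new representative map and
   written as `old_cluster_id, sequence_id, new_cluster_id` rows in input
   order.

Components are computed by graph union (networkx), not by literal
recursive traversal: recursion depth would be unbounded on large
components, and both formulations compute exactly the connected
components — the equivalence is pinned against a BFS oracle in the tests.

Consequences that the tests assert as invariants: the output partition is
always a coarsening of the input (whole clusters are unioned, never
split); every new label is an old representative id; the old→new map is a
lookup fixpoint (`map[map[x]] = map[x]`); with the internal backend the
procedure is idempotent — rerunning on its own output merges nothing; and
against any ground truth, homogeneity cannot increase.

## Search backends

**Internal.** Exhaustive affine-gap Smith–Waterman on every
representative pair, using Biopython's C `PairwiseAligner` in local mode
with BLOSUM62 and gap open 11 / extend 1 (a gap of length L costs
11 + L), the classic blastp defaults. Each unordered pair is aligned
once and mirrored: the scoring is symmetric, so raw score, identity and
coordinates are shared, and only the e-value differs between directions
through the query length m. Raw scores S become bit scores via the
gapped Karlin–Altschul parameters for this matrix/gap combination
(λ = 0.267, K = 0.041):
`bits = (λS − ln K)/ln 2`, `E = m·n·2^(−bits)` with n the summed length
of the representative set (no edge-effect length correction — the
simplest defensible search-space model; configurable via
`effective_db_letters`). A k-mer prefilter (default: at least one shared
3-mer) skips pairs that cannot be related; disabling it
(`min_kmer_matches=0`) can only add hits, never remove them (asserted as
a superset property). A directed hit is kept when `E ≤ 0.001` and query
coverage `(q_end − q_start + 1)/m ≥ 0.8`. Query-only coverage is used;
target coverage is not enforced. Selenocysteine and pyrrolysine are
outside the BLOSUM62 alphabet and are scored as Cys and Lys. Alignment
traceback ties are resolved by the aligner's fixed enumeration order
(first reported alignment), which is deterministic; the optimal *score*
is unique regardless.

**External.** Any 12-column BLAST-tabular file over the representative
ids. Hits are re-filtered against the same e-value and coverage
thresholds on load, so downstream behavior is backend-independent.
E-values from different tools are never compared numerically — each
models its search space differently — only through the threshold. A
sensitivity setting (default 7.5, the maximum of the usual external
search tool) is recorded in `SearchParams` for provenance and passed
through to external tools only; the internal backend is exhaustive and
has no sensitivity knob. External m8 files omit queries with no hits;
such representatives become isolated nodes and keep their clusters.

## Evaluation metrics

Implemented from the defining formulas (natural-log entropies) so results
do not depend on a particular library version; degenerate-case
conventions (single class, single cluster, vanishing denominators) follow
scikit-learn so numbers are comparable with the wider literature, and
agreement with scikit-learn to ≥10 decimals on random labelings is part
of the test suite.

* homogeneity `h = 1 − H(C|K)/H(C)` (1 when `H(C) = 0`),
  completeness `c = 1 − H(K|C)/H(K)` (1 when `H(K) = 0`),
  V-measure `v = 2hc/(h+c)` (0 when `h + c = 0`).
* ARI by pair counting:
  `(Σ_ij C(n_ij,2) − E)/(M − E)` with
  `E = Σ_i C(a_i,2)·Σ_j C(b_j,2)/C(N,2)`, `M = ½[Σ_i C(a_i,2) + Σ_j C(b_j,2)]`;
  1.0 when `M = E`.
* AMI `= (MI − E[MI])/(mean(H(C),H(K)) − E[MI])` with arithmetic-mean
  normalization and the *exact* hypergeometric `E[MI]` over tables with
  fixed margins, evaluated in log space with `gammaln`; verified against
  exhaustive enumeration of all contingency tables at small N.

Because AMI normalizes by entropies while ARI normalizes by pair counts,
AMI scores pure-but-fragmented solutions of imbalanced class structures
higher than ARI does; the suite asserts this direction on a constructed
imbalanced case.

## Synthetic study conditions

The generator emulates the essential structure of curated homology
benchmarks (families grouped under superfamilies) at desk scale. Defaults
— the conditions used by the acceptance checks and `scripts/acceptance.py`:

| parameter | default | meaning |
|---|---|---|
| `n_families` | 20 | independent family ancestors |
| `seqs_per_family` | 6 | members derived per ancestor |
| `seq_length` | 110 | residues per ancestor |
| `within_family_divergence` | 0.25 | substitution events per site, member vs ancestor |
| `indel_rate` | 0.01 | indel events per site (geometric length, mean 2) |
| `families_per_superfamily` | off | optional two-level hierarchy at divergence 0.45 |

Ancestors are drawn i.i.d. from the BLOSUM62 background frequencies;
substitution targets are drawn from the BLOSUM62-conditional distribution
`P(b|a) ∝ p_b·2^(s_ab/2)`, so diverged homologs still score well under the
matrix that searches for them — the property that makes e-value
reciprocity meaningful. The conditional's diagonal is substantial, so the
expected identity of a member to its ancestor is
`1 − d·(1 − p_same) ≈ 0.83` at d = 0.25 (checked against simulation),
and two members are ~65% identical. That sits in the operating regime
the merge targets: far enough apart that a 90%-identity greedy clusterer
(the baseline, which visits sequences longest-first and joins the first
representative at ≥90% identity and ≥0.8 coverage, CD-HIT style)
shatters every family into singletons, close enough that within-family
alignments remain overwhelmingly significant (e-values ≈ 10⁻⁴⁰ vs ≈ 10
for cross-family pairs at these lengths). At 20 × 6 sequences the whole
generate→over-split→merge→evaluate cycle runs in seconds on one core,
which is why the property checks can afford ten independent seeds.

What the generator does **not** model: phylogenetic correlation within a
family (members are i.i.d. draws from the ancestor), domain
architecture, compositional bias, disorder, and real length variation.
Passing tests therefore demonstrate the algorithm's correctness and its
qualitative behavior on over-split homologous groups — not the
quantitative gains on any real benchmark, where divergence is
heterogeneous and family sizes are heavy-tailed. On these clean
conditions the merge typically recovers the ground-truth families
exactly; real data yields partial gains instead.

## Numerical and design choices

* **Seed rule for merged labels.** "Label the component by one of its
  members" leaves the choice free; we pin it to the first appearance in
  the e-value-sorted reciprocal hit list so the output is deterministic
  and the label is always the component member with the most significant
  evidence. Component *structure* is independent of this choice.
* **Sort tie-breaks** (equal e-values): descending bitscore, then
  lexicographic pair — determinism only.
* **Round-trip-exact m8 writing.** Floats are serialized with `repr`
  (shortest exact form) rather than rounded columns, so
  write-then-read is the identity; rounded external files read fine.
* **Cluster-TSV hygiene.** Headerless by default; a first line whose
  tokens both look like column names is skipped. A representative that
  never lists itself as a member is accepted with a warning and injected
  into its own cluster; a representative listed as a member of a
  *different* cluster is a partition violation and an error.
* **Degenerate inputs.** Empty clustering, empty FASTA, duplicate ids,
  members under two representatives, negative e-values, and unknown ids
  in external hit tables are all rejected with named, one-line errors.

## Known limitations

* The internal aligner is exhaustive O(n²) in the number of
  representatives — intended for validation and moderate inputs; use an
  external search tool's m8 output for large representative sets.
* E-values use a fixed search-space product without length corrections;
  they are calibrated for thresholding, not for reporting significance.
* Merging never re-chooses a representative sequence (e.g. the longest
  member) and never splits clusters; an over-merged input cannot be
  repaired.
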