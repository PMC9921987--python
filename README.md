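# completplus

Post-processing for large-scale protein sequence clusterings: merge
clusters whose representatives are **reciprocal alignment hits**, raising
completeness at little cost to homogeneity.

## The problem

Greedy, heuristic clustering tools built for millions of protein sequences
(MMseqs2's cluster/linclust modules, CD-HIT, ...) never compare the
representatives of different clusters with each other. The result is an
*over-split* clustering: one protein family scattered across many small
clusters and singletons. Re-clustering from scratch at higher sensitivity
is expensive and breaks incremental workflows where batches of sequences
arrive over time.

`completplus` repairs such a clustering using only two small artifacts —
the representative sequences (FASTA) and the representative→member table
(two-column TSV) — without revisiting the full data:

1. align all cluster representatives against each other (internal
   Smith–Waterman backend, or ingest any search tool's BLAST-tabular
   output);
2. sort hits by e-value, drop self-hits, and keep pairs that are
   **reciprocal**: a hit in each direction passes the e-value threshold
   (default 0.001) and query coverage (default 0.8). Mutual *presence* is
   enough — mutual **best** is deliberately not required, which is what
   lets the merge out-coarsen connected-component clustering by raw-score
   best hits;
3. merge the connected components of the reciprocal-hit graph and relabel
   every sequence, writing a three-column table
   `old_cluster_id  sequence_id  new_cluster_id`.

Because the merge only ever unions whole clusters, the output partition is
a *coarsening* of the input: homogeneity h can only decrease, completeness
c can increase, and on over-split inputs the V-measure `v = 2hc/(h+c)`
rises.

The package also ships from-formula implementations of the evaluation
metrics (homogeneity, completeness, V-measure, AMI with exact
hypergeometric E[MI], ARI), a synthetic protein-family generator with
known family/superfamily ground truth, and a greedy over-splitting
baseline clusterer, so the whole pipeline is testable with no downloads.

## Worked example

Simulate 8 families of 5 members (~25 substitution events per 100 sites
from each family ancestor), over-split them with the 90%-identity greedy
baseline, then merge:

```sh
$ completplus simulate --families 8 --per-family 5 --length 100 \
    --divergence 0.25 --seed 7 --out-fasta seqs.fasta --out-truth truth.tsv
wrote 40 sequences in 8 families

$ completplus cluster-baseline --fasta seqs.fasta --out clusters.tsv
40 sequences -> 40 clusters

$ completplus run --fasta seqs.fasta --clusters clusters.tsv --out merged.tsv
clusters in: 40  clusters out: 8  merged components: 8  elapsed: 0.34s

$ completplus eval --pred clusters.tsv --truth truth.tsv
homogeneity	completeness	v_measure	ami	ari	n_items	n_classes	n_clusters
1.000000	0.563705	0.720987	0.000000	0.000000	40	8	40

$ completplus eval --pred merged.tsv --truth truth.tsv
homogeneity	completeness	v_measure	ami	ari	n_items	n_classes	n_clusters
1.000000	1.000000	1.000000	1.000000	1.000000	40	8	8
```

At 25% divergence the members of a family are only ~65% identical to each
other, so the 90%-identity baseline leaves every sequence a singleton:
perfect homogeneity (1.0, every cluster pure) but poor completeness
(0.56, families shattered) and chance-level AMI/ARI (0.0). The
representatives of a family are still highly significant alignment hits of
one another (e-values far below 0.001), so the merge fuses each family
back into one cluster and every metric reaches 1.0. The output table keeps
the old label next to the new one for easy comparison:

```
F002_S00	F002_S00	F002_S01
F001_S03	F001_S03	F001_S00
...
```

With a precomputed search (e.g. `mmseqs search ... --format-mode 0`,
sensitivity `-s 7.5`), skip the internal aligner:

```sh
completplus run --fasta reps.fasta --clusters clusters.tsv \
    --backend m8 --aln-file hits.m8 --out merged.tsv
```

External hits are re-filtered against the same e-value and coverage
thresholds, so the merge behaves identically whichever backend produced
the table.

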