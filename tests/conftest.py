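"""Shared fixtures: the worked two-cluster merge example and small random
sequence factories."""

from __future__ import annotations

import numpy as np
import pytest

from completplus.io_formats import Clustering, SequenceRecord
from completplus.synthetic import AMINO_ACIDS, BLOSUM62_BACKGROUND

# Two near-identical representative sequences (98- and 100-mers, two
# substitutions apart) for the worked merge example: clusters d1u9ca_ and
# d1n57a_ are reciprocal hits, and every sequence is relabeled d1u9ca_.
# The d1u9ca_ representative is the shorter query, so its directed hit has
# the smaller e-value and seeds the merged component's label.
TABLE1_SEQS = {
    "d1u9ca_": (
        "PITFRVPSNIGYKSICLASKPGVWSDIANMAVEGIDNICMHTFETSGEMN"
        "DASMFSILNRKILPKLLEAHDGTCAQEKLSMGSNARFININFIGEKGR"
    ),
    "d1n57a_": (
        "PITFRVPSNIGYKSICLASKPGVWSDIANMPVEGIDNICMHTFETSGEMN"
        "DASMFSILNRMILPKLLEAHDGTCAQEKLSMGSNARFININFIGEKGRRV"
    ),
}

TABLE1_PAIRS = [
    ("d1u9ca_", "d1u9ca_"),
    ("d1u9ca_", "d1pv2c_"),
    ("d1u9ca_", "d1pv2d_"),
    ("d1n57a_", "d1n57a_"),
    ("d1n57a_", "d1izya_"),
    ("d1n57a_", "d1izza_"),
]

TABLE1_EXPECTED_ROWS = [
    ("d1u9ca_", "d1u9ca_", "d1u9ca_"),
    ("d1u9ca_", "d1pv2c_", "d1u9ca_"),
    ("d1u9ca_", "d1pv2d_", "d1u9ca_"),
    ("d1n57a_", "d1n57a_", "d1u9ca_"),
    ("d1n57a_", "d1izya_", "d1u9ca_"),
    ("d1n57a_", "d1izza_", "d1u9ca_"),
]


@pytest.fixture
def table1_records() -> list[SequenceRecord]:
    return [SequenceRecord(i, s) for i, s in TABLE1_SEQS.items()]


@pytest.fixture
def table1_clustering() -> Clustering:
    return Clustering(list(TABLE1_PAIRS))


@pytest.fixture
def table1_files(tmp_path, table1_records):
    """(fasta_path, clusters_path) for the worked example, on disk."""
    fasta = tmp_path / "reps.fasta"
    fasta.write_text(
        "".join(f">{r.id}\n{r.residues}\n" for r in table1_records)
    )
    clusters = tmp_path / "clusters.tsv"
    clusters.write_text(
        "".join(f"{rep}\t{member}\n" for rep, member in TABLE1_PAIRS)
    )
    return fasta, clusters


def random_protein(rng: np.random.Generator, length: int) -> str:
    """One random protein sequence from the BLOSUM62 background."""
    return "".join(
        AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=BLOSUM62_BACKGROUND)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
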