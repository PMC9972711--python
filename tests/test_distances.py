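"""Hamming distances, alignment and the genotype graph."""

from __future__ import annotations

import shutil

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcrlineage import (
    SequenceRecord,
    ValidationError,
    align_sequences,
    build_graph,
    build_matrix,
    collapse_genotypes,
    hamming,
    simulate,
    SimConfig,
)
from bcrlineage.distances import min_connecting_delta

SEQ = st.text(alphabet="ACGTN-", min_size=1, max_size=30)


# ---------------------------------------------------------------------------
# hamming

@pytest.mark.parametrize("a, b, expected", [
    ("ACGT", "ACGT", 0),
    ("ACGT", "ACGA", 1),
    ("AC-T", "ACGT", 1),   # gap vs base is a mismatch
    ("A--T", "A--T", 0),   # shared gaps carry no signal
    ("ANGT", "AAGT", 1),   # N is a fifth symbol: mismatches every base
    ("N-GT", "NAGT", 1),   # ... and the gap, but matches itself
])
def test_hamming_examples(a, b, expected):
    assert hamming(a, b) == expected


def test_hamming_rejects_unequal_lengths():
    with pytest.raises(ValidationError):
        hamming("ACG", "ACGT")


@settings(max_examples=80, deadline=None)
@given(st.integers(1, 25), st.data())
def test_hamming_is_a_metric(n, data):
    a = data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
    b = data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
    c = data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
    assert hamming(a, a) == 0
    assert hamming(a, b) == hamming(b, a) >= 0
    assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


# ---------------------------------------------------------------------------
# distance matrix

def _table(seqs, root=0):
    records = [SequenceRecord(f"g{i}", s) for i, s in enumerate(seqs)]
    return collapse_genotypes(records, root_id=f"g{root}")


def test_single_genotype_matrix_is_zero():
    m = build_matrix(_table(["ACGT"]))
    assert m.raw.shape == (1, 1) and m.raw[0, 0] == 0


def test_matrix_matches_pairwise_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(5):
        n = int(rng.integers(2, 30))
        L = int(rng.integers(5, 40))
        seqs = set()
        while len(seqs) < n:
            seqs.add("".join(rng.choice(list("ACGTN"), size=L)))
        table = _table(sorted(seqs))
        m = build_matrix(table)
        for i, gi in enumerate(table.genotypes):
            for j, gj in enumerate(table.genotypes):
                assert m.raw[i, j] == hamming(gi.seq, gj.seq)
        assert np.allclose(m.normalised, m.raw / table.alignment_length)


# ---------------------------------------------------------------------------
# alignment

def test_mode_none_returns_equal_length_input_unchanged():
    recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "AGGT")]
    assert align_sequences(recs, mode="none") == recs


def test_mode_none_rejects_unequal_lengths():
    recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACG")]
    with pytest.raises(ValidationError, match="equal lengths"):
        align_sequences(recs, mode="none")


def test_builtin_alignment_conserves_content():
    recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACT")]
    aligned = align_sequences(recs, mode="builtin")
    assert len({len(r.seq) for r in aligned}) == 1
    for before, after in zip(recs, aligned):
        assert after.degapped() == before.seq


def test_builtin_alignment_of_clonal_variants_has_no_gap_columns():
    sim = simulate(SimConfig(seed=5, root_length=60, observation_rate=1.0))
    recs = sim.records[:20]
    aligned = align_sequences(recs, mode="builtin")
    assert all("-" not in r.seq for r in aligned)
    assert [r.seq for r in aligned] == [r.seq for r in recs]


@settings(max_examples=40, deadline=None)
@given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=20),
                min_size=1, max_size=6))
def test_degap_after_builtin_alignment_restores_input(seqs):
    recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    aligned = align_sequences(recs, mode="builtin")
    assert len({len(r.seq) for r in aligned}) == 1
    for before, after in zip(recs, aligned):
        assert after.degapped() == before.seq


def test_external_aligner_mafft_round_trip():
    # mafft ships with the environment; a missing binary is an actionable error
    recs = [SequenceRecord("a", "ACGTACGTAA"), SequenceRecord("b", "ACGTCGTAA"),
            SequenceRecord("c", "ACGTACGTAA")]
    if shutil.which("mafft") is None:
        with pytest.raises(Exception, match="not found on PATH"):
            align_sequences(recs, mode="external")
        return
    aligned = align_sequences(recs, mode="external")
    assert len({len(r.seq) for r in aligned}) == 1
    for before, after in zip(recs, aligned):
        assert after.degapped() == before.seq


# ---------------------------------------------------------------------------
# genotype graph

def test_graph_without_delta_is_complete():
    table = _table(["AAAA", "AAAC", "AACC", "ACCC"])
    g = build_graph(build_matrix(table), table.abundances(), table.root_label)
    assert g.graph.number_of_edges() == 6


def test_delta_prunes_long_edges_only():
    table = _table(["AAAAA", "AAAAC", "AAACC", "AACCC"])
    m = build_matrix(table)
    g = build_graph(m, table.abundances(), table.root_label, delta=2)
    weights = [d for _, _, d in g.graph.edges(data="weight")]
    assert max(weights) <= 2
    assert g.graph.number_of_edges() == 5  # only the weight-3 edge is gone


def test_delta_zero_disconnects_distinct_genotypes():
    table = _table(["AAAA", "AAAC", "AACC"])
    m = build_matrix(table)
    with pytest.raises(ValidationError, match="disconnect"):
        build_graph(m, table.abundances(), table.root_label, delta=0)


def test_disconnection_error_reports_smallest_viable_delta():
    table = _table(["AAAAA", "AAAAC", "CCCCC"])
    m = build_matrix(table)
    with pytest.raises(ValidationError, match=str(min_connecting_delta(m))):
        build_graph(m, table.abundances(), table.root_label, delta=1)
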