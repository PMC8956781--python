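import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gaoscope.annotation import (
    AlignmentHit,
    HitParseError,
    UNASSIGNED,
    assign_function,
    assign_taxonomy,
    compute_abundance,
    filter_hits_for_lca,
    read_hit_table,
    write_hit_table,
)


def make_hit(query="q1", subject="s1", evalue=1e-30, bitscore=200.0, **kw):
    base = dict(
        query_id=query, subject_id=subject, percent_identity=90.0,
        align_len=100, mismatches=5, gap_opens=1, q_start=1, q_end=100,
        s_start=1, s_end=100, evalue=evalue, bitscore=bitscore,
    )
    base.update(kw)
    return AlignmentHit(**base)


class TestReadHitTable:
    def test_empty_file(self):
        assert read_hit_table(io.StringIO("")) == {}

    def test_single_row_scientific_notation(self):
        row = "q1\ts1\t95.5\t100\t4\t0\t1\t100\t1\t100\t1e-30\t250\n"
        hits = read_hit_table(io.StringIO("# comment\n" + row))
        assert list(hits) == ["q1"]
        assert hits["q1"][0].evalue == 1e-30
        assert hits["q1"][0].bitscore == 250.0

    @pytest.mark.parametrize(
        "row,match",
        [
            ("q1\ts1\t95.5\t100\n", "expected 12 columns"),
            ("q1\ts1\t95.5\t100\t4\t0\t1\t100\t1\t100\tbogus\t250\n", "line 1"),
        ],
    )
    def test_malformed_rows_report_line_number(self, row, match):
        with pytest.raises(HitParseError, match=match):
            read_hit_table(io.StringIO(row))

    def test_roundtrip_random_hits(self, tmp_path):
        rng = np.random.default_rng(0)
        hits = [
            make_hit(
                query=f"q{rng.integers(0, 20)}", subject=f"s{i}",
                evalue=float(10.0 ** -rng.integers(3, 40)),
                bitscore=float(np.round(rng.uniform(50, 500), 1)),
                align_len=int(rng.integers(30, 300)),
            )
            for i in range(200)
        ]
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        reloaded = [h for group in read_hit_table(path).values() for h in group]
        assert sorted(reloaded, key=lambda h: h.subject_id) == sorted(
            hits, key=lambda h: h.subject_id
        )


class TestFilterHitsForLCA:
    def test_cutoff_then_window(self):
        evalues = [1e-30, 5e-30, 2e-29, 1e-3]
        hits = [make_hit(subject=f"s{i}", evalue=e) for i, e in enumerate(evalues)]
        kept = filter_hits_for_lca(hits)
        assert sorted(h.evalue for h in kept) == [1e-30, 5e-30]

    def test_cutoff_excludes_all(self):
        assert filter_hits_for_lca([make_hit(evalue=1e-4)]) == []

    def test_all_equal_evalues_all_retained(self):
        hits = [make_hit(subject=f"s{i}", evalue=1e-10) for i in range(4)]
        assert len(filter_hits_for_lca(hits)) == 4

    @given(st.lists(st.floats(min_value=1e-60, max_value=1.0), min_size=1, max_size=20))
    def test_subset_and_order_invariant(self, evalues):
        hits = [make_hit(subject=f"s{i}", evalue=e) for i, e in enumerate(evalues)]
        kept = filter_hits_for_lca(hits)
        assert set(kept) <= set(hits)
        kept_rev = filter_hits_for_lca(list(reversed(hits)))
        assert set(kept) == set(kept_rev)


class TestAssignTaxonomy:
    def test_single_genus(self, tiny_tree):
        hits = {"u1": [make_hit(subject="s1")]}
        out = assign_taxonomy(hits, tiny_tree, {"s1": "G1"})
        assert out == {"u1": "G1"}

    def test_two_genera_resolve_to_family(self, tiny_tree):
        hits = {"u1": [make_hit(subject="a", evalue=1e-30),
                       make_hit(subject="b", evalue=2e-30)]}
        out = assign_taxonomy(hits, tiny_tree, {"a": "G1", "b": "G2"})
        assert out == {"u1": "F"}

    def test_window_excludes_distant_genus(self, tiny_tree):
        # second hit outside the x10 window never reaches the LCA
        hits = {"u1": [make_hit(subject="a", evalue=1e-30),
                       make_hit(subject="b", evalue=2e-29)]}
        out = assign_taxonomy(hits, tiny_tree, {"a": "G1", "b": "G2"})
        assert out == {"u1": "G1"}

    def test_unmappable_subjects_give_unassigned(self, tiny_tree):
        out = assign_taxonomy({"u1": [make_hit(subject="x")]}, tiny_tree, {})
        assert out == {"u1": UNASSIGNED}

    def test_taxon_missing_from_tree_is_error(self, tiny_tree):
        with pytest.raises(KeyError, match="s1"):
            assign_taxonomy({"u1": [make_hit(subject="s1")]}, tiny_tree,
                            {"s1": "ghost"})


class TestAssignFunction:
    def test_single_qualifying_hit(self):
        out = assign_function({"u1": [make_hit(subject="s1")]}, {"s1": "k1"})
        assert out == {"u1": "k1"}

    def test_max_bitscore_wins(self):
        hits = {"u1": [make_hit(subject="a", bitscore=250),
                       make_hit(subject="b", bitscore=300)]}
        assert assign_function(hits, {"a": "k1", "b": "k2"}) == {"u1": "k2"}

    def test_tie_breaks_to_smaller_subject_id(self):
        h1 = make_hit(subject="sA", bitscore=300, evalue=1e-20)
        h2 = make_hit(subject="sB", bitscore=300, evalue=1e-20)
        smap = {"sA": "kA", "sB": "kB"}
        assert assign_function({"u": [h1, h2]}, smap) == {"u": "kA"}
        assert assign_function({"u": [h2, h1]}, smap) == {"u": "kA"}

    def test_cutoff_and_unmapped_excluded(self):
        hits = {"u1": [make_hit(subject="bad", evalue=1e-3, bitscore=999),
                       make_hit(subject="unmapped", bitscore=500)]}
        assert assign_function(hits, {"bad": "k1"}) == {"u1": UNASSIGNED}


class TestComputeAbundance:
    def test_single_unigene_is_one(self):
        ab = compute_abundance(pd.DataFrame({"s1": [42]}, index=["u1"]), {"u1": 500})
        assert ab.loc["u1", "s1"] == 1.0

    def test_equal_count_per_length(self):
        counts = pd.DataFrame({"s1": [100, 50]}, index=["u1", "u2"])
        ab = compute_abundance(counts, {"u1": 1000, "u2": 500})
        assert ab["s1"].tolist() == [0.5, 0.5]

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(100, 4)),
            index=[f"u{i}" for i in range(100)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 3000, 100).astype(float),
                            index=counts.index)
        ab = compute_abundance(counts, lengths)
        assert np.allclose(ab.sum(axis=0), 1.0, atol=1e-9)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 20, 30]}, index=list("abc"))
        lengths = {"a": 100, "b": 200, "c": 300}
        ab1 = compute_abundance(counts, lengths)
        ab2 = compute_abundance(counts * 17, lengths)
        pd.testing.assert_frame_equal(ab1, ab2)

    def test_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["u1", "u2"])
        with pytest.raises(ValueError, match="zero total"):
            compute_abundance(counts, {"u1": 100, "u2": 100})

    def test_nonpositive_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["u1"])
        with pytest.raises(ValueError, match="positive"):
            compute_abundance(counts, {"u1": 0})
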