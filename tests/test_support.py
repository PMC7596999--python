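"""Read-support tracing and the fragment/support/guided filters."""

import numpy as np
import pytest

from lrannot.collapse import WobbleThresholds
from lrannot.models import Annotation
from lrannot.support import (
    ReadSupport,
    filter_by_support,
    guided_filter,
    is_fragment_of,
    read_support_levels,
    remove_fragments,
)

from conftest import make_model

W = WobbleThresholds(a=10, m=5, z=10)
CHAIN = ((100, 200), (400, 500), (700, 800))


class TestReadSupportLevels:
    def test_single_collapse_is_identity(self):
        rs = read_support_levels({"run1": {"T1": ["r1", "r2"], "T2": ["r3"]}})
        assert rs.transcripts == {
            "T1": {("run1", "r1"), ("run1", "r2")},
            "T2": {("run1", "r3")},
        }
        assert rs.read_count("T1") == 2

    def test_merge_unions_member_support(self):
        traces = {"c1": {"A": ["r1", "r2"]}, "c2": {"B": ["r3"]}}
        merges = [("m", {"M1": [("c1", "A"), ("c2", "B")]})]
        rs = read_support_levels(traces, merges)
        assert rs.transcripts["M1"] == {("c1", "r1"), ("c1", "r2"), ("c2", "r3")}
        assert rs.source_count("M1") == 2

    def test_support_composes_through_two_merge_layers(self):
        traces = {"c1": {"A": ["r1"]}, "c2": {"B": ["r2"]}}
        merges = [
            ("m1", {"X": [("c1", "A")]}),
            ("m2", {"Y": [("m1", "X"), ("c2", "B")]}),
        ]
        rs = read_support_levels(traces, merges)
        assert rs.transcripts == {"Y": {("c1", "r1"), ("c2", "r2")}}

    def test_total_reads_conserved(self):
        rng = np.random.default_rng(0)
        trace = {
            f"T{i}": [f"r{i}_{k}" for k in range(int(rng.integers(1, 6)))] for i in range(20)
        }
        merges = [("m", {f"M{i//2}": [("c", f"T{i}"), ("c", f"T{i+1}")] for i in range(0, 20, 2)})]
        rs = read_support_levels({"c": trace}, merges)
        total = {rid for pairs in rs.transcripts.values() for _, rid in pairs}
        assert len(total) == sum(len(v) for v in trace.values())

    def test_dangling_contributor_named_in_error(self):
        with pytest.raises(ValueError, match="c:GHOST"):
            read_support_levels({"c": {"A": ["r1"]}}, [("m", {"M": [("c", "GHOST")]})])


class TestRemoveFragments:
    def test_internal_fragment_removed(self):
        full = make_model("G1.1", CHAIN, gene="G1")
        frag = make_model("G1.2", [(150, 200), (400, 480)], gene="G1")
        ann = Annotation.from_models([full, frag])
        kept = remove_fragments(ann, m=0)
        assert [m.transcript_id for m in kept] == ["G1.1"]

    def test_5prime_truncation_sharing_3prime_end_retained(self):
        full = make_model("G1.1", CHAIN, gene="G1")
        trunc = make_model("G1.2", CHAIN[1:], gene="G1")  # same 3' end: not a fragment
        kept = remove_fragments(Annotation.from_models([full, trunc]), m=0)
        assert len(kept) == 2

    def test_single_exon_inside_an_exon_removed(self):
        full = make_model("G1.1", CHAIN, gene="G1")
        mono = make_model("G1.2", [(420, 480)], gene="G1")
        kept = remove_fragments(Annotation.from_models([full, mono]), m=0)
        assert [m.transcript_id for m in kept] == ["G1.1"]

    def test_exact_duplicate_not_self_removed(self):
        a = make_model("G1.1", CHAIN, gene="G1")
        b = make_model("G1.2", CHAIN, gene="G1")
        kept = remove_fragments(Annotation.from_models([a, b]), m=0)
        assert len(kept) == 2  # "longer on both ends" is strict

    def test_fifteen_model_fixture_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(19)
        models = []
        base_chain = tuple((k * 500, k * 500 + 200) for k in range(5))
        for i in range(15):
            kind = rng.random()
            if kind < 0.4:  # sub-chain fragment
                lo = int(rng.integers(0, 3))
                hi = int(rng.integers(lo + 1, 5))
                ex = list(base_chain[lo : hi + 1])
                ex[0] = (ex[0][0] + int(rng.integers(1, 100)), ex[0][1])
                ex[-1] = (ex[-1][0], ex[-1][1] - int(rng.integers(1, 100)))
                models.append(make_model(f"G1.{i}", ex, gene="G1"))
            elif kind < 0.6:  # mono-exon
                s = int(rng.integers(0, 2200))
                models.append(make_model(f"G1.{i}", [(s, s + int(rng.integers(30, 150)))], gene="G1"))
            else:  # full-length variants
                models.append(make_model(f"G1.{i}", base_chain, gene="G1"))
        ann = Annotation.from_models(models)
        for m_w in (0, 5):
            kept = {x.transcript_id for x in remove_fragments(ann, m=m_w)}
            want = {
                c.transcript_id
                for c in models
                if not any(o is not c and is_fragment_of(c, o, m_w) for o in models)
            }
            assert kept == want

    def test_longest_model_of_locus_never_removed(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            models = []
            for i in range(n):
                s = int(rng.integers(0, 200))
                e = s + int(rng.integers(100, 2000))
                models.append(make_model(f"T{i}", [(s, e)], gene=f"T{i}"))
            longest = max(models, key=lambda m: m.end - m.start)
            kept = remove_fragments(Annotation.from_models(models), m=0)
            assert longest.transcript_id in {m.transcript_id for m in kept}


class TestFilterBySupport:
    def _fixture(self):
        ann = Annotation.from_models(
            [
                make_model("G1.1", CHAIN, gene="G1"),
                make_model("G1.2", CHAIN[1:], gene="G1"),
                make_model("G2.1", [(5000, 5400)], gene="G2"),
            ]
        )
        rs = ReadSupport(
            transcripts={
                "G1.1": {("cell1", "r1"), ("cell1", "r2"), ("cell2", "r3")},
                "G1.2": {("cell1", "r4")},
                "G2.1": {("cell2", "r5")},
            }
        )
        return ann, rs

    def test_min_count_one_is_identity(self):
        ann, rs = self._fixture()
        assert len(filter_by_support(ann, rs, min_count=1)) == len(ann)

    def test_monotone_decreasing_in_min_count(self):
        ann, rs = self._fixture()
        sizes = [len(filter_by_support(ann, rs, min_count=k)) for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_source_unit_keeps_multi_cell_models_only(self):
        # requiring support from >= 2 sources mimics the two-flowcell rule
        ann, rs = self._fixture()
        kept = filter_by_support(ann, rs, min_count=2, unit="sources")
        assert [m.transcript_id for m in kept] == ["G1.1"]

    def test_gene_level_drops_whole_gene(self):
        ann, rs = self._fixture()
        kept = filter_by_support(ann, rs, level="gene", min_count=2)
        assert {m.transcript_id for m in kept} == {"G1.1", "G1.2"}

    def test_survivors_equal_counting_oracle(self):
        rng = np.random.default_rng(31)
        models = [
            make_model(f"G{i}.1", [(i * 1000, i * 1000 + 500)], gene=f"G{i}") for i in range(12)
        ]
        ann = Annotation.from_models(models)
        rs = ReadSupport(
            transcripts={
                m.transcript_id: {
                    ("s", f"r{m.transcript_id}_{k}") for k in range(int(rng.integers(0, 5)))
                }
                for m in models
            }
        )
        for k in range(1, 5):
            kept = {m.transcript_id for m in filter_by_support(ann, rs, min_count=k)}
            want = {t for t, pairs in rs.transcripts.items() if len(pairs) >= k}
            assert kept == want


class TestGuidedFilter:
    def test_exact_subset_retained_with_reference_coordinates(self):
        ref = Annotation.from_models(
            [
                make_model("R.1", CHAIN, gene="R"),
                make_model("R2.1", [(5000, 5500)], gene="R2"),
            ]
        )
        lr = Annotation.from_models([make_model("L.1", ((415, 500), (700, 790)), gene="L")])
        kept, _ = guided_filter(lr, ref, W)
        assert len(kept) == 1
        assert kept.models[0].exons == CHAIN

    def test_disjoint_annotations_empty(self):
        ref = Annotation.from_models([make_model("R.1", CHAIN, gene="R")])
        lr = Annotation.from_models([make_model("L.1", ((9000, 9300),), gene="L")])
        kept, _ = guided_filter(lr, ref, W)
        assert len(kept) == 0

    def test_retained_set_equals_nocap_match_oracle(self):
        from lrannot.collapse import match_nocap

        rng = np.random.default_rng(6)
        ref_models, lr_models = [], []
        for i in range(10):
            base = 4000 * i
            chain = tuple((base + k * 400, base + k * 400 + 150) for k in range(3))
            ref_models.append(make_model(f"R{i}.1", chain, gene=f"R{i}"))
            if rng.random() < 0.5:  # matching truncation
                lr_models.append(make_model(f"L{i}.1", chain[1:], gene=f"L{i}"))
            else:  # shifted junction: should not match
                bad = tuple((s + 40, e + 40) for s, e in chain[1:])
                lr_models.append(make_model(f"L{i}.1", bad, gene=f"L{i}"))
        ref = Annotation.from_models(ref_models)
        lr = Annotation.from_models(lr_models)
        kept, report = guided_filter(lr, ref, W)
        matched_lr = {
            l.transcript_id
            for l in lr_models
            if any(match_nocap(l.exons, r.exons, "+", W) for r in ref_models)
        }
        retained_lr = {
            mid
            for tid in (m.transcript_id for m in kept)
            for lbl, mid in report.transcripts[tid]
            if lbl == "longread"
        }
        assert retained_lr == matched_lr
        # output junction chains are a subset of reference chains
        ref_sjs = {m.junctions for m in ref_models}
        assert all(m.junctions in ref_sjs for m in kept)
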