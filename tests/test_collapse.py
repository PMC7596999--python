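"""Wobble matching, read grouping, splice-junction ranking and full collapse."""

import numpy as np
import pytest

from lrannot.collapse import (
    CollapseConfig,
    ReadGroup,
    WobbleThresholds,
    collapse,
    detect_genomic_polya,
    group_reads,
    match_capped,
    match_nocap,
    models_as_alignments,
    rank_splice_junctions,
)
from lrannot.profile import (
    SUBSTITUTION,
    GenomeAccessor,
    MismatchEvent,
)
from lrannot.sim import SimConfig, simulate

from conftest import make_alignment

W = WobbleThresholds(a=10, m=5, z=10)
CHAIN = ((100, 200), (400, 500), (700, 800))


def shift_boundary(chain, exon, side, delta):
    chain = [list(e) for e in chain]
    chain[exon][0 if side == "start" else 1] += delta
    return tuple(tuple(e) for e in chain)


class TestMatchCapped:
    def test_identical_chains_match(self):
        assert match_capped(CHAIN, CHAIN, "+", W)

    def test_donor_shift_at_threshold_inclusive(self):
        shifted = shift_boundary(CHAIN, 0, "end", W.m)
        assert match_capped(CHAIN, shifted, "+", W)

    def test_donor_shift_beyond_threshold_fails(self):
        shifted = shift_boundary(CHAIN, 0, "end", W.m + 1)
        assert not match_capped(CHAIN, shifted, "+", W)

    def test_exon_count_mismatch_fails(self):
        assert not match_capped(CHAIN, CHAIN[:2], "+", W)

    def test_end_tolerances_are_strand_aware(self):
        # shifting the genomic-left start by a (>m, <=a) is 5' wobble on +
        shifted = shift_boundary(CHAIN, 0, "start", W.a)
        assert match_capped(CHAIN, shifted, "+", W)
        # on -, the genomic-left end is the 3' end: z applies
        assert match_capped(CHAIN, shifted, "-", W)
        wz = WobbleThresholds(a=10, m=5, z=3)
        assert not match_capped(CHAIN, shifted, "-", wz)


def brute_force_nocap(x, y, strand, w):
    """Independent suffix matcher: try all alignments of the shorter chain's
    junctions onto a 3'-terminal suffix of the longer chain's."""
    if len(x) == len(y):
        return match_capped(x, y, strand, w)
    if not (x[0][0] < y[-1][1] and y[0][0] < x[-1][1]):
        return False
    short, long = (x, y) if len(x) < len(y) else (y, x)
    sj_s = [(a[1], b[0]) for a, b in zip(short, short[1:])]
    sj_l = [(a[1], b[0]) for a, b in zip(long, long[1:])]
    k = len(sj_s)
    if strand == "+":
        cand = sj_l[len(sj_l) - k:] if k else []
        if abs(short[-1][1] - long[-1][1]) > w.z:
            return False
        corr = long[len(long) - len(short)]
        if not (corr[0] - w.a <= short[0][0] < corr[1]):
            return False
    else:
        cand = sj_l[:k]
        if abs(short[0][0] - long[0][0]) > w.z:
            return False
        corr = long[len(short) - 1]
        if not (corr[0] < short[-1][1] <= corr[1] + w.a):
            return False
    return all(
        abs(a[0] - b[0]) <= w.m and abs(a[1] - b[1]) <= w.m for a, b in zip(sj_s, cand)
    )


class TestMatchNocap:
    def test_5prime_truncation_merges(self):
        truncated = CHAIN[1:]  # shares the terminal junction and 3' end
        assert match_nocap(CHAIN, truncated, "+", W)
        assert not match_capped(CHAIN, truncated, "+", W)

    def test_truncation_with_shifted_junction_fails(self):
        truncated = shift_boundary(CHAIN[1:], 0, "end", W.m + 1)
        assert not match_nocap(CHAIN, truncated, "+", W)

    def test_single_exon_read_inside_terminal_exon(self):
        read = ((705, 798),)
        assert match_nocap(CHAIN, read, "+", W)
        # on the minus strand the 3'-terminal exon is the genomic-left one
        read_minus = ((103, 195),)
        assert match_nocap(CHAIN, read_minus, "-", W)
        assert not match_nocap(CHAIN, read, "-", W)  # |ΔTES| way over z

    def test_minus_strand_truncation_uses_left_prefix(self):
        truncated = CHAIN[:2]  # keeps the genomic-left junctions = 3' side on -
        assert match_nocap(CHAIN, truncated, "-", W)
        assert not match_nocap(CHAIN, truncated, "+", W)  # 3' ends disagree on +

    def test_equal_exon_counts_degenerate_to_capped(self):
        shifted = shift_boundary(CHAIN, 1, "start", W.m)
        assert match_nocap(CHAIN, shifted, "+", W) == match_capped(CHAIN, shifted, "+", W)

    def test_matches_brute_force_suffix_matcher(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(300):
            base = tuple(
                (int(s), int(s) + int(rng.integers(40, 120)))
                for s in np.cumsum(rng.integers(150, 400, size=int(rng.integers(1, 5))))
            )
            # derive a perturbed/truncated partner
            drop = int(rng.integers(0, len(base)))
            other = base[drop:] if rng.random() < 0.7 else tuple(
                (s + int(rng.integers(-8, 9)), e + int(rng.integers(-8, 9)))
                for s, e in base
            )
            if not other or any(s >= e for s, e in other):
                continue
            for strand in "+-":
                assert match_nocap(base, other, strand, W) == brute_force_nocap(
                    base, other, strand, W
                ), (base, other, strand)
            n_checked += 1
        assert n_checked > 200


class TestGrouping:
    def test_wobble_walking_chains_staggered_reads(self):
        m = 10
        reads = [
            make_alignment("r1", [(0, 100)]),
            make_alignment("r2", [(m, 100 + m)]),
            make_alignment("r3", [(2 * m, 100 + 2 * m)]),
        ]
        cfg = CollapseConfig(mode="capped", wobble=WobbleThresholds(a=m, m=m, z=m))
        groups = group_reads(reads, cfg)
        assert len(groups) == 1 and len(groups[0].members) == 3
        # outer pair alone exceeds the threshold
        groups2 = group_reads([reads[0], reads[2]], cfg)
        assert len(groups2) == 2

    def test_opposite_strands_never_group(self):
        reads = [
            make_alignment("r1", [(0, 100)], strand="+"),
            make_alignment("r2", [(0, 100)], strand="-"),
        ]
        cfg = CollapseConfig(mode="capped", wobble=W)
        assert len(group_reads(reads, cfg)) == 2

    @pytest.mark.parametrize("mode", ["capped", "no_cap"])
    def test_grouping_equals_transitive_closure_oracle(self, mode):
        rng = np.random.default_rng(7)
        cfg = CollapseConfig(mode=mode, wobble=W)
        for _ in range(60):
            reads = []
            for i in range(int(rng.integers(2, 9))):
                origin = int(rng.choice([0, 30, 600]))
                n = int(rng.integers(1, 4))
                pos = origin + int(rng.integers(0, 30))
                exons = []
                for _k in range(n):
                    ln = int(rng.integers(40, 120))
                    exons.append((pos, pos + ln))
                    pos += ln + int(rng.integers(60, 150))
                reads.append(make_alignment(f"r{i}", exons))
            got = group_reads(reads, cfg)
            got_sets = {frozenset(m.read_id for m in g.members) for g in got}
            want_sets = _brute_closure(reads, cfg)
            assert got_sets == want_sets

    def test_sum_of_group_sizes_is_read_count(self):
        rng = np.random.default_rng(3)
        reads = [
            make_alignment(f"r{i}", [(int(p), int(p) + 80)])
            for i, p in enumerate(rng.integers(0, 2000, size=40))
        ]
        groups = group_reads(reads, CollapseConfig(mode="capped", wobble=W))
        assert sum(len(g.members) for g in groups) == 40


def _brute_closure(reads, cfg):
    from lrannot.collapse import match_chains

    n = len(reads)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = reads[i], reads[j]
            if a.strand != b.strand:
                continue
            if a.start >= b.end or b.start >= a.end:
                continue
            if match_chains(a.blocks, b.blocks, a.strand, cfg.wobble, cfg.mode):
                adj[i].add(j)
    seen, comps = set(), set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.add(frozenset(reads[k].read_id for k in comp))
    return comps


class TestSjRanking:
    def _group(self):
        clean = make_alignment("clean", [(0, 100), (203, 300)])
        noisy = [
            make_alignment(
                f"noisy{i}",
                [(0, 100), (200, 300)],
                events=[
                    MismatchEvent(95, SUBSTITUTION, 1),
                    MismatchEvent(98, SUBSTITUTION, 1),
                ],
            )
            for i in range(3)
        ]
        return ReadGroup(chrom="chr1", strand="+", members=[clean] + noisy)

    def test_clean_flank_beats_higher_coverage(self):
        chosen = rank_splice_junctions(self._group(), window=20, ranking=True)
        assert chosen == [(100, 203)]

    def test_coverage_wins_with_ranking_off(self):
        chosen = rank_splice_junctions(self._group(), window=20, ranking=False)
        assert chosen == [(100, 200)]

    def test_unanimous_candidate_trivially_chosen(self):
        members = [make_alignment(f"r{i}", [(0, 100), (200, 300)]) for i in range(4)]
        g = ReadGroup(chrom="chr1", strand="+", members=members)
        assert rank_splice_junctions(g, 20) == [(100, 200)]


class TestGenomicPolya:
    def test_downstream_a_tract_flagged(self):
        genome = GenomeAccessor({"c": "C" * 100 + "A" * 20 + "C" * 100})
        assert detect_genomic_polya(genome, "c", "+", 100, window=20, frac=0.7)

    def test_downstream_c_not_flagged(self):
        genome = GenomeAccessor({"c": "C" * 220})
        assert not detect_genomic_polya(genome, "c", "+", 100, window=20, frac=0.7)

    def test_minus_strand_reads_upstream_t(self):
        genome = GenomeAccessor({"c": "C" * 80 + "T" * 20 + "C" * 120})
        assert detect_genomic_polya(genome, "c", "-", 100, window=20, frac=0.7)

    def test_window_truncated_at_contig_end(self):
        genome = GenomeAccessor({"c": "C" * 100 + "AAAAA"})
        assert detect_genomic_polya(genome, "c", "+", 100, window=20, frac=0.7)

    def test_planted_tracts_recovered_in_simulation(self):
        res = simulate(SimConfig(seed=5, n_genes=8, polya_plant_fraction=0.5))
        genome = GenomeAccessor(res.genome)
        for gid, tids in res.truth.loci.items():
            m = res.truth.get(tids[0])
            flagged = detect_genomic_polya(genome, m.chrom, m.strand, m.tes, 20, 0.7)
            assert flagged == (gid in res.polya_genes), gid


class TestCollapse:
    def _reads_for(self, chain, n, prefix="r", strand="+"):
        return [make_alignment(f"{prefix}{i}", chain, strand=strand) for i in range(n)]

    def test_ten_identical_reads_one_model(self, flat_genome):
        reads = self._reads_for(CHAIN, 10)
        ann, rep = collapse(reads, CollapseConfig(mode="capped", wobble=W), flat_genome)
        assert len(ann) == 1
        assert ann.models[0].read_count == 10
        assert ann.models[0].exons == CHAIN

    def test_truncations_merge_only_in_nocap(self, flat_genome):
        reads = self._reads_for(CHAIN, 10) + self._reads_for(CHAIN[1:], 5, prefix="t")
        capped, _ = collapse(reads, CollapseConfig(mode="capped", wobble=W), flat_genome)
        nocap, _ = collapse(reads, CollapseConfig(mode="no_cap", wobble=W), flat_genome)
        assert len(capped) == 2
        assert len(nocap) == 1
        assert nocap.models[0].read_count == 15

    def test_lde_zero_keeps_only_clean_reads_and_recovers_truth_sjs(self, flat_genome):
        clean = self._reads_for(CHAIN, 4)
        noisy = [
            make_alignment(
                f"n{i}",
                shift_boundary(CHAIN, 0, "end", 3),
                events=[MismatchEvent(196, SUBSTITUTION, 1)],
            )
            for i in range(4)
        ]
        cfg = CollapseConfig(mode="capped", wobble=W, lde_window=20, lde_max=0)
        ann, rep = collapse(clean + noisy, cfg, flat_genome)
        assert rep.n_pass == 4
        assert {r for r, (ok, _) in rep.read_decisions.items() if not ok} == {
            "n0", "n1", "n2", "n3"
        }
        assert ann.models[0].junctions == ((200, 400), (500, 700))

    def test_read_count_conservation_and_mode_ordering(self, tmp_path):
        res = simulate(SimConfig(seed=13, degradation_fraction=0.3))
        genome = GenomeAccessor(res.genome)
        reads = [make_alignment(r.read_id, r.blocks, strand=r.strand) for r in res.reads]
        counts = {}
        for mode in ("capped", "no_cap"):
            ann, rep = collapse(reads, CollapseConfig(mode=mode, wobble=WobbleThresholds(100, 10, 100)), genome)
            assert sum(m.read_count for m in ann) == len(reads)
            counts[mode] = len(ann)
        assert counts["no_cap"] <= counts["capped"]

    @pytest.mark.parametrize("mode", ["capped", "no_cap"])
    def test_collapse_is_idempotent(self, mode, flat_genome):
        res = simulate(SimConfig(seed=21, degradation_fraction=0.2, n_genes=6))
        genome = GenomeAccessor(res.genome)
        reads = [make_alignment(r.read_id, r.blocks, strand=r.strand) for r in res.reads]
        cfg = CollapseConfig(mode=mode, wobble=WobbleThresholds(100, 10, 100))
        ann1, _ = collapse(reads, cfg, genome)
        ann2, _ = collapse(models_as_alignments(ann1), cfg, genome)
        chains1 = sorted((m.chrom, m.strand, m.exons) for m in ann1)
        chains2 = sorted((m.chrom, m.strand, m.exons) for m in ann2)
        assert chains1 == chains2

    def test_chosen_sjs_always_come_from_a_read(self, flat_genome):
        rng = np.random.default_rng(17)
        reads = []
        for i in range(30):
            base = 1000 * int(rng.integers(0, 3))
            chain = (
                (base, base + 100 + int(rng.integers(-5, 6))),
                (base + 200 + int(rng.integers(-5, 6)), base + 300),
            )
            reads.append(make_alignment(f"r{i}", chain))
        ann, _ = collapse(reads, CollapseConfig(mode="capped", wobble=W), flat_genome)
        observed = {j for r in reads for j in (tuple(x) for x in [r.blocks[0][1:2] + r.blocks[1][0:1]])}
        for m in ann:
            for j in m.junctions:
                assert j in observed
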