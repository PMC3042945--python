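"""Assembler correctness: overlap detection, layout, consensus, conservation."""

import numpy as np
import pytest

from gametotk import assembly as asm
from gametotk import synthetic_data as sim
from gametotk.assembly import AssemblyResult, Placement, Unigene


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_best_overlap(a, b, min_overlap, min_identity):
    """Exhaustive dovetail scan: try every diagonal and both orientations.

    Returns the best (identity, length, orientation) via full global
    alignment of each implied overlap, or None.  Independent of the
    k-mer seeded path it checks.
    """
    import edlib

    best = None
    for ori, bs in (("+", b), ("-", asm.revcomp(b))):
        for diag in range(-(len(bs) - min_overlap), len(a) - min_overlap + 1):
            a0, b0 = max(0, diag), max(0, -diag)
            span = min(len(a) - a0, len(bs) - b0)
            if span < min_overlap:
                continue
            res = edlib.align(a[a0 : a0 + span], bs[b0 : b0 + span], mode="NW", task="path")
            ident, cols, _, _ = asm._identity_from_cigar(res["cigar"], res["editDistance"])
            if cols >= min_overlap and ident >= min_identity:
                cand = (ident, cols, ori)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    return best


class TestFindOverlaps:
    def test_identical_reads(self, rng):
        s = random_dna(rng, 300)
        ovs = asm.find_overlaps([("a", s), ("b", s)])
        assert len(ovs) == 1
        assert ovs[0].identity == 1.0
        assert ovs[0].length == 300

    def test_min_overlap_boundary(self, rng):
        s = random_dna(rng, 400)
        a, b = s[:212], s[188:]  # 24 bp shared
        ovs = asm.find_overlaps([("a", a), ("b", b)], k=16, min_overlap=25)
        assert ovs == []
        b2 = s[187:]  # 25 bp shared
        ovs = asm.find_overlaps([("a", a), ("b", b2)], k=16, min_overlap=25)
        assert len(ovs) == 1 and ovs[0].length == 25

    def test_reverse_complement_overlap(self, rng):
        s = random_dna(rng, 500)
        a, b = s[:300], asm.revcomp(s[200:])
        ovs = asm.find_overlaps([("a", a), ("b", b)])
        assert len(ovs) == 1
        assert ovs[0].orientation == "-"
        assert ovs[0].length == 100

    def test_matches_brute_force_on_random_pairs(self, rng):
        """Seeded detection agrees with an exhaustive all-diagonal scan."""
        n_with = n_without = 0
        for trial in range(50):
            if trial % 2 == 0:
                s = random_dna(rng, 420)
                cut = int(rng.integers(120, 300))
                a, b = s[: cut + 80], s[cut:]
                if rng.random() < 0.5:
                    b = asm.revcomp(b)
            else:
                a, b = random_dna(rng, 300), random_dna(rng, 300)
            expected = brute_force_best_overlap(a, b, 40, 0.94)
            got = asm.find_overlaps([("a", a), ("b", b)], min_overlap=40, min_identity=0.94)
            if expected is None:
                assert got == []
                n_without += 1
            else:
                assert len(got) == 1
                assert got[0].identity == pytest.approx(expected[0], abs=1e-9)
                assert got[0].length == expected[1]
                assert got[0].orientation == expected[2]
                n_with += 1
        assert n_with >= 10 and n_without >= 10


class TestAssemblePrimary:
    def test_single_read_is_singleton(self, rng):
        res = asm.assemble_primary([("only", random_dna(rng, 250))])
        assert len(res.unigenes) == 1
        assert res.unigenes[0].category == "singleton"
        assert res.unigenes[0].depth == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_tiling_reads_reconstruct_transcript(self, seed):
        """20 error-free staggered reads from one 1 kb transcript -> exact consensus."""
        rng = np.random.default_rng(seed)
        tx = random_dna(rng, 1000)
        reads = []
        for i in range(20):
            start = min(i * 50, 1000 - 300)
            reads.append((f"r{i:02d}", tx[start : start + 300]))
        res = asm.assemble_primary(reads)
        contigs = [u for u in res.unigenes if u.category == "primary_contig"]
        assert len(contigs) == 1
        assert len(res.unigenes) == 1
        assert contigs[0].consensus == tx
        assert len(contigs[0].members) == 20

    def test_similar_transcripts_stay_separate(self, rng):
        """Two 90 %-identical transcripts cannot co-assemble at 94 % identity."""
        t1 = random_dna(rng, 800)
        t2 = list(t1)
        # plant evenly spaced substitutions: 10% divergence
        for i in range(0, 800, 10):
            t2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t2[i]]
        t2 = "".join(t2)
        reads = []
        for j, t in enumerate((t1, t2)):
            for i in range(10):
                start = min(i * 55, 800 - 300)
                reads.append((f"t{j}r{i}", t[start : start + 300]))
        res = asm.assemble_primary(reads, min_identity=0.94)
        contigs = [u for u in res.unigenes if u.category == "primary_contig"]
        assert len(contigs) == 2
        members = [{m.read_id[:2] for m in c.members} for c in contigs]
        assert all(len(group) == 1 for group in members), "no cross-placement"

    def test_read_conservation(self, small_library):
        cfg, ts, reads, _ = small_library
        res = asm.assemble_primary([(r.read_id, r.sequence) for r in reads])
        placed = [m.read_id for u in res.unigenes for m in u.members]
        assert sorted(placed + res.discarded_reads) == sorted(r.read_id for r in reads)
        stats = res.step_stats["primary"]
        assert (
            stats["reads_assembled"] + stats["reads_discarded"] + stats["singletons"]
            == stats["reads_in"]
        )

    def test_unigene_count_monotone_in_identity(self):
        """Raising min_identity never decreases the unigene count."""
        for seed in range(4):
            cfg = sim.SimConfig(
                n_genes=6, n_reads=80, seed=seed, substitution_rate=0.01,
                adapter_5p_prob=0, adapter_3p_prob=0, polyA_prob=0,
                homopolymer_indel_rate=0,
            )
            ts = sim.simulate_transcriptome(cfg)
            reads, _ = sim.simulate_reads(ts, cfg)
            pairs = [(r.read_id, r.sequence) for r in reads]
            counts = [
                len(asm.assemble_primary(pairs, min_identity=mi).unigenes)
                for mi in (0.90, 0.94, 0.98)
            ]
            assert counts == sorted(counts)


class TestAssembleSecondary:
    def _primary_of(self, unigenes, n_reads):
        return AssemblyResult(
            unigenes,
            [],
            {
                "primary": {
                    "reads_in": n_reads,
                    "reads_assembled": sum(
                        len(u.members) for u in unigenes if u.category != "singleton"
                    ),
                    "reads_discarded": 0,
                    "singletons": sum(1 for u in unigenes if u.category == "singleton"),
                    "primary_contigs": sum(
                        1 for u in unigenes if u.category == "primary_contig"
                    ),
                    "secondary_contigs": 0,
                    "unigenes": len(unigenes),
                }
            },
        )

    def test_disjoint_unigenes_unchanged(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        unis = [
            Unigene("U1", a, "primary_contig", [Placement("r1", 0, 400, "+"), Placement("r2", 0, 400, "+")]),
            Unigene("U2", b, "singleton", [Placement("r3", 0, 400, "+")]),
        ]
        res = asm.assemble_secondary(self._primary_of(unis, 3))
        assert sorted(u.category for u in res.unigenes) == ["primary_contig", "singleton"]
        assert len(res.unigenes) == 2

    def test_exact_end_overlap_merges(self, rng):
        s = random_dna(rng, 1000)
        a, b = s[:600], s[400:]
        unis = [
            Unigene("U1", a, "primary_contig", [Placement("r1", 0, 600, "+"), Placement("r2", 0, 600, "+")]),
            Unigene("U2", b, "primary_contig", [Placement("r3", 0, 600, "+"), Placement("r4", 0, 600, "+")]),
        ]
        res = asm.assemble_secondary(self._primary_of(unis, 4))
        assert len(res.unigenes) == 1
        merged = res.unigenes[0]
        assert merged.category == "secondary_contig"
        assert len(merged.consensus) == 600 + 600 - 200
        assert merged.consensus == s

    def test_secondary_never_discards_or_increases(self, small_library):
        _, _, reads, _ = small_library
        primary = asm.assemble_primary([(r.read_id, r.sequence) for r in reads])
        final = asm.assemble_secondary(primary)
        assert final.step_stats["secondary"]["reads_discarded"] == 0
        assert len(final.unigenes) <= len(primary.unigenes)
        placed = [m.read_id for u in final.unigenes for m in u.members]
        assert sorted(placed) == sorted(
            m.read_id for u in primary.unigenes for m in u.members
        )


class TestComputeDepth:
    def test_singleton_depth_one(self, rng):
        u = Unigene("U", random_dna(rng, 100), "singleton", [Placement("r", 0, 100, "+")])
        assert asm.compute_depth(u) == 1.0

    def test_two_full_span_reads(self, rng):
        u = Unigene(
            "U",
            random_dna(rng, 100),
            "primary_contig",
            [Placement("a", 0, 100, "+"), Placement("b", 0, 100, "-")],
        )
        assert asm.compute_depth(u) == 2.0

    def test_matches_pileup_oracle(self, rng):
        cons = random_dna(rng, 500)
        members = []
        pileup = np.zeros(500)
        for i in range(12):
            s = int(rng.integers(0, 400))
            e = int(rng.integers(s + 10, 500))
            members.append(Placement(f"r{i}", s, e, "+"))
            pileup[s:e] += 1
        u = Unigene("U", cons, "primary_contig", members)
        assert asm.compute_depth(u) == pytest.approx(pileup.mean())

    def test_zero_length_consensus_rejected(self):
        u = Unigene("U", "", "singleton", [Placement("r", 0, 0, "+")])
        with pytest.raises(ValueError):
            asm.compute_depth(u)
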