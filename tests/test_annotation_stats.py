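"""ORF calls, GO-slim projection, Fisher/BH enrichment and set overlaps."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import hypergeom

from gametotk import annotation_stats as anno
from gametotk import fixtures as fx
from gametotk.assembly import revcomp


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_longest_orf(seq):
    """Enumerate all six frames codon by codon; longest stop-to-stop stretch.

    Segment length counts nucleotides including a terminating stop codon.
    Returns (best nucleotide length, best peptide length).
    """
    from Bio.Seq import Seq

    best_nt = best_aa = -1
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else revcomp(seq)
        off = abs(frame) - 1
        aa = "".join(
            str(Seq(s[i : i + 3]).translate()) for i in range(off, len(s) - 2, 3)
        )
        segments = aa.split("*")
        for si, seg in enumerate(segments):
            nt = 3 * len(seg) + (3 if si < len(segments) - 1 else 0)
            if nt > best_nt:
                best_nt, best_aa = nt, len(seg)
    return best_nt, best_aa


class TestLongestOrf:
    def test_textbook_translation(self):
        call = anno.longest_orf("ATGAAATAG")
        assert call.frame == 1
        assert call.peptide == "MK"
        assert call.interval == (0, 6)

    def test_single_stop_codon_degenerate(self):
        """A lone stop codon yields a zero-length peptide, leftmost frame."""
        call = anno.longest_orf("TAA")
        assert call.peptide == ""
        assert call.frame == 1
        assert call.interval == (0, 0)

    def test_too_short(self):
        assert anno.longest_orf("AC") is None

    def test_matches_exhaustive_six_frame_oracle(self, rng):
        for _ in range(200):
            seq = random_dna(rng, 300)
            call = anno.longest_orf(seq)
            best_nt, best_aa = brute_force_longest_orf(seq)
            terminated = 3 * len(call.peptide) < best_nt
            assert 3 * len(call.peptide) + (3 if terminated else 0) == best_nt
            assert len(call.peptide) >= best_aa - 1  # stop-terminated tie margin
            assert "*" not in call.peptide
            lo, hi = call.interval
            assert (hi - lo) % 3 == 0
            # the called interval really translates to the called peptide
            sub = seq[lo:hi] if call.frame > 0 else revcomp(seq[lo:hi])
            from Bio.Seq import Seq

            assert str(Seq(sub).translate()) == call.peptide


@pytest.fixture(scope="module")
def ontology(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "toy.obo"
    slim = fx.toy_ontology_obo(path)
    return anno.OntologyGraph.from_obo(path)


class TestMapToSlim:
    def test_slim_term_maps_to_itself(self, ontology):
        out = anno.map_to_slim({"s": {"GO:0000012"}}, ontology)
        assert "GO:0000012" in out["s"]

    def test_leaf_reaches_slim_root(self, ontology):
        out = anno.map_to_slim({"s": {"GO:0000110"}}, ontology)
        # carbon fixation is_a photosynthesis (slim) is_a metabolic process (slim)
        assert {"GO:0000012", "GO:0000010", "GO:0000001"} <= out["s"]

    def test_part_of_traversed(self, ontology):
        out = anno.map_to_slim({"s": {"GO:0000120"}}, ontology)
        assert "GO:0000020" in out["s"]  # thylakoid part_of plastid
        only_isa = anno.map_to_slim({"s": {"GO:0000120"}}, ontology, relations=("is_a",))
        assert "GO:0000020" not in only_isa["s"]

    def test_unknown_terms_skipped(self, ontology):
        out = anno.map_to_slim({"s": {"GO:9999999"}}, ontology)
        assert out["s"] == set()

    def test_matches_transitive_closure_oracle(self, rng):
        """Random layered DAGs: slim image == ancestor closure ∩ slim."""
        for trial in range(20):
            g = nx.MultiDiGraph()
            n = 25
            for i in range(n):
                g.add_node(f"T{i}", namespace="ns")
            for i in range(1, n):
                for p in rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False):
                    rel = "is_a" if rng.random() < 0.7 else "part_of"
                    g.add_edge(f"T{i}", f"T{int(p)}", key=rel)
            slim = {f"T{int(i)}" for i in rng.choice(n, size=6, replace=False)}
            graph = anno.OntologyGraph(g, slim)
            terms = {f"T{int(i)}" for i in rng.choice(n, size=4, replace=False)}
            got = anno.map_to_slim({"s": terms}, graph)["s"]
            closure = set()
            for t in terms:
                closure |= {t} | nx.descendants(g, t)  # edges point child->parent
            assert got == closure & slim

    def test_monotone_in_annotations(self, ontology):
        small = anno.map_to_slim({"s": {"GO:0000110"}}, ontology)["s"]
        large = anno.map_to_slim({"s": {"GO:0000110", "GO:0000130"}}, ontology)["s"]
        assert small <= large

    def test_cycle_rejected(self):
        g = nx.MultiDiGraph()
        g.add_edge("A", "B", key="is_a")
        g.add_edge("B", "A", key="is_a")
        with pytest.raises(ValueError):
            anno.OntologyGraph(g, set())


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of hypergeometric point probabilities <= that of the observed table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(x) for x in range(max(0, col1 - (c + d)), min(row1, col1) + 1)
        if rv.pmf(x) <= p_obs * (1 + 1e-9)
    )


def bh_oracle(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, pvals[i] * m / (rank + 1))
        q[i] = prev
    return q


class TestEnrichment:
    def test_identical_frequencies_null(self):
        test = {f"t{i}": {"GO:1"} for i in range(10)}
        ref = {f"r{i}": {"GO:1"} for i in range(10)}
        results = anno.enrichment(test, ref)
        assert all(r.p == pytest.approx(1.0) for r in results)
        assert not any(r.significant for r in results)

    def test_symmetric_table_p_one(self):
        test = {f"t{i}": ({"GO:1"} if i < 5 else set()) for i in range(10)}
        ref = {f"r{i}": ({"GO:1"} if i < 5 else set()) for i in range(10)}
        (r,) = anno.enrichment(test, ref)
        assert (r.a, r.b, r.c, r.d) == (5, 5, 5, 5)
        assert r.p == pytest.approx(1.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            anno.enrichment({"a": {"GO:1"}}, {})

    def test_matches_closed_form_oracles(self, rng):
        """50 random 2x2 tables: p from the hypergeometric sum, q from step-up BH."""
        tables = [
            tuple(int(x) for x in rng.integers(0, 40, size=4)) for _ in range(50)
        ]
        for i, (a, b, c, d) in enumerate(tables):
            term = f"GO:{i:03d}"
            test = {f"t{j}": ({term} if j < a else set()) for j in range(a + b)}
            ref = {f"r{j}": ({term} if j < c else set()) for j in range(c + d)}
            if a + b == 0 or c + d == 0:
                continue
            results = anno.enrichment(test, ref)
            if not results:
                continue
            (r,) = results
            assert r.p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-6)
        # BH on one joint run with many terms
        pvals = rng.uniform(0, 1, size=30)
        q = bh_oracle(pvals)
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_direction_flips_when_sets_swap(self):
        test = {f"t{i}": ({"GO:1"} if i < 8 else set()) for i in range(10)}
        ref = {f"r{i}": ({"GO:1"} if i < 2 else set()) for i in range(10)}
        (fwd,) = anno.enrichment(test, ref)
        (rev,) = anno.enrichment(ref, test)
        assert fwd.p == pytest.approx(rev.p)
        assert {fwd.direction, rev.direction} == {"over", "under"}

    def test_all_null_never_significant(self):
        test = {f"t{i}": {"GO:1", "GO:2"} for i in range(6)}
        ref = {f"r{i}": {"GO:1", "GO:2"} for i in range(6)}
        results = anno.enrichment(test, ref, alpha=0.99)
        assert not any(r.significant for r in results)

    def test_q_monotone_in_p_rank(self, rng):
        test = {
            f"t{i}": {f"GO:{j}" for j in rng.choice(12, size=3, replace=False)}
            for i in range(40)
        }
        ref = {
            f"r{i}": {f"GO:{j}" for j in rng.choice(12, size=2, replace=False)}
            for i in range(60)
        }
        results = anno.enrichment(test, ref)
        by_p = sorted(results, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert qs == sorted(qs)


class TestDetectionRate:
    def test_no_hits(self):
        detected, total, frac = anno.detection_rate({}, ["g1", "g2"])
        assert (detected, total, frac) == (0, 2, 0.0)

    @pytest.mark.parametrize(
        "detected,total,pct", [(333, 357, 93.3), (754, 959, 78.6)]
    )
    def test_published_conserved_gene_rates(self, detected, total, pct):
        genes = [f"g{i}" for i in range(total)]
        hits = {f"g{i}": [120] for i in range(detected)}
        d, t, frac = anno.detection_rate(hits, genes)
        assert (d, t) == (detected, total)
        assert round(100 * frac, 1) == pct

    def test_alignment_length_strictly_greater(self):
        hits = {"g1": [30], "g2": [31]}
        d, _, _ = anno.detection_rate(hits, ["g1", "g2"], min_aln_residues=30)
        assert d == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            anno.detection_rate({}, [])


class TestSetOverlap:
    def test_disjoint(self):
        out = anno.set_overlap({"A": {"x"}, "B": {"y"}})
        assert out["A&B"] == 0 and out["A"] == 1 and out["B"] == 1

    def test_identical_sets(self):
        s = {"a", "b", "c"}
        out = anno.set_overlap({"A": set(s), "B": set(s)})
        assert out["A&B"] == 3 and out["A"] == 0 and out["B"] == 0

    def test_matches_inclusion_exclusion(self, rng):
        universe = [f"id{i}" for i in range(200)]
        for _ in range(25):
            sets = {
                name: {u for u in universe if rng.random() < p}
                for name, p in (("A", 0.3), ("B", 0.4), ("C", 0.2))
            }
            out = anno.set_overlap(sets, universe=set(universe))
            # bitmask recomputation
            regions = {}
            for u in universe:
                key = "&".join(sorted(n for n in sets if u in sets[n]))
                regions[key or "outside"] = regions.get(key or "outside", 0) + 1
            for key, count in regions.items():
                assert out[key] == count
            assert sum(out.values()) == 200

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            anno.set_overlap({"A": set()})
        with pytest.raises(ValueError):
            anno.set_overlap({n: set() for n in "ABCD"})
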