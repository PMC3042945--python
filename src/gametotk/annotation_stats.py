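"""ORF extraction, GO-slim mapping, Fisher enrichment and set overlaps.

GO-slim mapping follows the true-path rule: every annotated term
contributes each slim term found among its ancestors-or-self reachable
over ``is_a`` (and, by default, ``part_of``) edges; ontology namespaces
are kept separate by construction since ancestor traversal never crosses
them.  Enrichment compares per-term annotated-sequence counts between a
test and a reference set with a two-tailed Fisher's exact test and
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OntologyGraph",
    "EnrichmentResult",
    "OrfCall",
    "longest_orf",
    "map_to_slim",
    "enrichment",
    "detection_rate",
    "set_overlap",
]

_CODON_TABLE = {}


def _codon_table():
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@dataclass
class OrfCall:
    seq_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    interval: tuple[int, int]  # on the input nucleotide sequence, 0-based half-open
    peptide: str


_FRAMES = (1, 2, 3, -1, -2, -3)


def longest_orf(sequence: str, seq_id: str = "") -> OrfCall | None:
    """Longest stop-to-stop segment over all six frames, no start codon required.

    Segments are bounded by stop codons or the frame's edges.  Segment
    length is measured in nucleotides and includes the terminating stop
    codon when present (the stop is part of the reading frame even though
    it contributes no residue); ties are broken by frame order
    (+1, +2, +3, -1, -2, -3), then leftmost within the frame.  The
    reported interval covers the peptide-coding nucleotides only.
    Returns None for sequences shorter than one codon.
    """
    from .assembly import revcomp

    sequence = sequence.upper()
    n = len(sequence)
    if n < 3:
        return None
    table = _codon_table()
    best: OrfCall | None = None
    best_nt = -1
    for frame in _FRAMES:
        offset = abs(frame) - 1
        strand_seq = sequence if frame > 0 else revcomp(sequence)
        n_codons = (n - offset) // 3
        aa = "".join(
            table.get(strand_seq[offset + 3 * i : offset + 3 * i + 3], "X")
            for i in range(n_codons)
        )
        segments = aa.split("*")
        start = 0
        for si, segment in enumerate(segments):
            seg_start = start
            start += len(segment) + 1
            terminated = si < len(segments) - 1
            nt_len = 3 * len(segment) + (3 if terminated else 0)
            if nt_len <= best_nt:
                continue  # ties keep the earlier frame / leftmost call
            nt_lo = offset + 3 * seg_start
            nt_hi = nt_lo + 3 * len(segment)
            if frame > 0:
                interval = (nt_lo, nt_hi)
            else:
                interval = (n - nt_hi, n - nt_lo)
            best = OrfCall(seq_id=seq_id, frame=frame, interval=interval, peptide=segment)
            best_nt = nt_len
    return best


class OntologyGraph:
    """A gene-ontology DAG with a designated slim subset.

    Wraps a :mod:`networkx` DiGraph with child->parent edges typed
    ``is_a`` or ``part_of``.  Construction fails on cyclic input.
    """

    def __init__(self, graph: nx.MultiDiGraph, slim_subset: set[str]):
        self.graph = graph
        missing = {t for t in slim_subset if t not in graph}
        if missing:
            raise ValueError(f"slim terms absent from the ontology: {sorted(missing)}")
        self.slim_subset = set(slim_subset)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")

    @classmethod
    def from_obo(cls, path, slim_subset: set[str] | None = None):
        """Load an OBO 1.2 ontology; slim terms carry a ``subset`` tag or are given."""
        import obonet

        g = obonet.read_obo(path)
        if slim_subset is None:
            slim_subset = {
                t
                for t, data in g.nodes(data=True)
                if any("slim" in s for s in data.get("subset", []))
            }
        return cls(g, slim_subset)

    def ancestors_or_self(self, term: str, relations: tuple[str, ...] = ("is_a", "part_of")) -> set[str]:
        if term not in self.graph:
            return set()
        out = {term}
        stack = [term]
        while stack:
            node = stack.pop()
            for _, parent, key in self.graph.out_edges(node, keys=True):
                if key in relations and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out


def map_to_slim(
    annotations: dict[str, set[str]],
    graph: OntologyGraph,
    relations: tuple[str, ...] = ("is_a", "part_of"),
) -> dict[str, set[str]]:
    """Project per-sequence GO annotations onto the slim subset (true-path rule).

    Unknown term ids are skipped.  Each annotated term contributes every
    slim term among its ancestors-or-self.
    """
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for seq_id, terms in annotations.items():
        slim: set[str] = set()
        for t in terms:
            if t not in cache:
                cache[t] = graph.ancestors_or_self(t, relations) & graph.slim_subset
            slim |= cache[t]
        out[seq_id] = slim
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    a: int  # test sequences annotated with the term
    b: int  # test sequences without it
    c: int  # reference sequences with it
    d: int  # reference sequences without it
    p: float
    q: float
    direction: str  # over | under
    significant: bool


def enrichment(
    test: dict[str, set[str]],
    reference: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Two-tailed Fisher's exact test per term with Benjamini-Hochberg FDR.

    Counting unit is the annotated sequence: a term's 2x2 table is
    (sequences-with, sequences-without) in each of the test and reference
    sets.  Direction is by odds ratio (test frequency vs reference
    frequency).  Both inputs should already be slim-mapped when slim-level
    enrichment is wanted.
    """
    if not reference:
        raise ValueError("reference annotation set is empty")
    n_test = len(test)
    n_ref = len(reference)
    terms = sorted({t for s in test.values() for t in s} | {t for s in reference.values() for t in s})
    rows = []
    for term in terms:
        a = sum(1 for s in test.values() if term in s)
        c = sum(1 for s in reference.values() if term in s)
        b, d = n_test - a, n_ref - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, b, c, d, p))
    if not rows:
        return []
    pvals = [r[5] for r in rows]
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for (term, a, b, c, d, p), q, sig in zip(rows, qvals, reject):
        freq_test = a / n_test if n_test else 0.0
        freq_ref = c / n_ref if n_ref else 0.0
        direction = "over" if freq_test > freq_ref else "under"
        out.append(
            EnrichmentResult(
                term_id=term,
                a=a,
                b=b,
                c=c,
                d=d,
                p=float(p),
                q=float(q),
                direction=direction,
                significant=bool(sig),
            )
        )
    return out


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term_id for r in results],
            "test_with": [r.a for r in results],
            "test_without": [r.b for r in results],
            "ref_with": [r.c for r in results],
            "ref_without": [r.d for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )


def detection_rate(
    hits_per_gene: dict[str, list[int]],
    reference_list: list[str],
    min_aln_residues: int = 30,
) -> tuple[int, int, float]:
    """Fraction of reference genes with a hit longer than ``min_aln_residues``.

    ``hits_per_gene`` maps gene id -> alignment lengths (residues) of its
    hits.  A gene counts as detected when at least one hit is strictly
    longer than the threshold.
    """
    if not reference_list:
        raise ValueError("reference gene list is empty")
    detected = sum(
        1
        for g in reference_list
        if any(l > min_aln_residues for l in hits_per_gene.get(g, []))
    )
    total = len(reference_list)
    return detected, total, detected / total


def set_overlap(
    named_sets: dict[str, set[str]], universe: set[str] | None = None
) -> dict[str, int]:
    """Venn region counts for two or three named sets.

    Region keys are '&'-joined sorted membership signatures (e.g. 'A',
    'A&B', 'A&B&C'); the empty-signature region ('outside') is included
    when a universe is supplied.
    """
    if not 2 <= len(named_sets) <= 3:
        raise ValueError("set_overlap supports 2 or 3 sets")
    names = sorted(named_sets)
    regions: dict[str, int] = {}
    for mask in product([False, True], repeat=len(names)):
        inside = [n for n, m in zip(names, mask) if m]
        if not inside:
            continue
        region = set.intersection(*(named_sets[n] for n in inside))
        for n, m in zip(names, mask):
            if not m:
                region = region - named_sets[n]
        regions["&".join(inside)] = len(region)
    if universe is not None:
        union = set.union(*named_sets.values())
        regions["outside"] = len(universe - union)
    return regions
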