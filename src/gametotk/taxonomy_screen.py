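"""Taxonomic screening of homology hits: best-hit and LCA assignment.

Consumes standard 13-column tabular homology output (the 12 BLAST outfmt-6
columns plus a subject taxon id), maps each query onto a taxonomy tree by
its best hit and by the lowest common ancestor of its qualifying hits, and
summarizes assignments by nested taxonomic categories.  A separate screen
flags putative genomic (plastid) contamination from hit spans against an
annotated organellar genome.

The LCA rule: a hit qualifies when its bitscore is strictly greater than a
floor (default 75) and within 10 % of the query's top bitscore
(multiplicative, >= 0.9 x top); an LCA is assigned only when at least
three hits qualify, otherwise the query is left "not assigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HitRecord",
    "TaxonomyTree",
    "TaxAssignment",
    "load_hits",
    "assign_lca",
    "assign_all",
    "taxonomic_summary",
    "plastid_screen",
    "NOT_ASSIGNED",
]

NOT_ASSIGNED = "not assigned"

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "staxids",
]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    taxon_id: int
    evalue: float
    bitscore: float
    aln_len: int
    pct_identity: float
    sstart: int = 0  # 1-based, inclusive, as printed by search engines
    send: int = 0


class TaxonomyTree:
    """A rooted taxonomy from (taxon_id, parent_id, rank, name) rows.

    The root is self-parented.  Unresolvable taxon ids in queries are
    mapped to None by callers.
    """

    def __init__(self, nodes):
        self.parent: dict[int, int] = {}
        self.rank: dict[int, str] = {}
        self.name: dict[int, str] = {}
        roots = []
        for taxon_id, parent_id, rank, name in nodes:
            taxon_id, parent_id = int(taxon_id), int(parent_id)
            self.parent[taxon_id] = parent_id
            self.rank[taxon_id] = rank
            self.name[taxon_id] = name
            if taxon_id == parent_id:
                roots.append(taxon_id)
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for t in self.parent:
            if self.path_to_root(t) is None:
                raise ValueError(f"cycle or dangling parent at taxon {t}")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(
            path, sep="\t", names=["taxon_id", "parent_id", "rank", "name"], header=0
        )
        return cls(df.itertuples(index=False, name=None))

    def to_tsv(self, path) -> None:
        rows = [
            (t, self.parent[t], self.rank[t], self.name[t]) for t in sorted(self.parent)
        ]
        pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"]).to_csv(
            path, sep="\t", index=False
        )

    def __contains__(self, taxon_id) -> bool:
        return taxon_id in self.parent

    def path_to_root(self, taxon_id: int) -> list[int] | None:
        """Ancestor path from the node to the root, inclusive of both."""
        if taxon_id not in self.parent:
            return None
        path = [taxon_id]
        seen = {taxon_id}
        while path[-1] != self.root:
            nxt = self.parent.get(path[-1])
            if nxt is None or nxt in seen:
                return None
            path.append(nxt)
            seen.add(nxt)
        return path

    def lca(self, taxa) -> int:
        """Deepest node that is an ancestor-or-self of every given taxon."""
        taxa = [t for t in taxa if t in self.parent]
        if not taxa:
            raise ValueError("no resolvable taxa")
        paths = [self.path_to_root(t)[::-1] for t in taxa]  # root first
        lca = self.root
        for level in range(min(len(p) for p in paths)):
            nodes = {p[level] for p in paths}
            if len(nodes) == 1:
                lca = nodes.pop()
            else:
                break
        return lca

    def is_within(self, taxon_id: int, clade: int) -> bool:
        path = self.path_to_root(taxon_id)
        return path is not None and clade in path


@dataclass
class TaxAssignment:
    query_id: str
    best_hit_taxon: int | None
    lca_taxon: int | str  # taxon id, or NOT_ASSIGNED


def load_hits(
    path, evalue_max: float = 1e-10, top_n: int = 10
) -> dict[str, list[HitRecord]]:
    """Load a 13-column tabular hit file, filter and truncate per query.

    Hits with evalue <= ``evalue_max`` are kept; per query only the
    ``top_n`` highest bitscores are retained (ties at the cutoff broken by
    subject id, lexicographically, for determinism).
    """
    try:
        df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        return {}
    if df["bitscore"].isna().any() or df["staxids"].isna().any():
        bad = int(df.index[df["bitscore"].isna() | df["staxids"].isna()][0]) + 1
        raise ValueError(f"{path}: malformed hit row at line {bad}")
    df = df[df["evalue"] <= evalue_max]
    df = df.sort_values(
        ["qseqid", "bitscore", "sseqid"], ascending=[True, False, True]
    )
    out: dict[str, list[HitRecord]] = {}
    for q, grp in df.groupby("qseqid", sort=True):
        grp = grp.head(top_n)
        out[str(q)] = [
            HitRecord(
                query_id=str(r.qseqid),
                subject_id=str(r.sseqid),
                taxon_id=int(r.staxids),
                evalue=float(r.evalue),
                bitscore=float(r.bitscore),
                aln_len=int(r.length),
                pct_identity=float(r.pident),
                sstart=int(r.sstart),
                send=int(r.send),
            )
            for r in grp.itertuples(index=False)
        ]
    return out


def assign_lca(
    hits: list[HitRecord],
    tree: TaxonomyTree,
    min_hits: int = 3,
    min_bitscore: float = 75.0,
    top_fraction: float = 0.10,
) -> TaxAssignment:
    """Best-hit and LCA taxon for one query's (bitscore-sorted) hit list."""
    if not hits:
        raise ValueError("assign_lca requires at least one hit")
    query_id = hits[0].query_id
    ordered = sorted(hits, key=lambda h: (-h.bitscore, h.subject_id))
    best = ordered[0]
    best_taxon = best.taxon_id if best.taxon_id in tree else None
    top = best.bitscore
    qualifying = [
        h.taxon_id
        for h in ordered
        if h.bitscore > min_bitscore
        and h.bitscore >= (1.0 - top_fraction) * top
        and h.taxon_id in tree
    ]
    if len(qualifying) >= min_hits:
        lca = tree.lca(qualifying)
    else:
        lca = NOT_ASSIGNED
    return TaxAssignment(query_id=query_id, best_hit_taxon=best_taxon, lca_taxon=lca)


def assign_all(
    hits_by_query: dict[str, list[HitRecord]],
    tree: TaxonomyTree,
    min_hits: int = 3,
    min_bitscore: float = 75.0,
    top_fraction: float = 0.10,
) -> list[TaxAssignment]:
    return [
        assign_lca(hits, tree, min_hits, min_bitscore, top_fraction)
        for _, hits in sorted(hits_by_query.items())
    ]


def taxonomic_summary(
    assignments: list[TaxAssignment],
    tree: TaxonomyTree,
    category_nodes: dict[str, int],
) -> pd.DataFrame:
    """Counts and percentages of queries falling within each named clade.

    Categories may be nested; each is counted independently (a query in a
    child clade also counts for every ancestral category).  Percentages
    are relative to the number of queries with hits.  Both the best-hit
    and the LCA assignment are tabulated.
    """
    for name, node in category_nodes.items():
        if node not in tree:
            raise ValueError(f"unknown category node {name} ({node})")
    n = len(assignments)
    rows = []
    for name, node in category_nodes.items():
        best = sum(
            1
            for a in assignments
            if a.best_hit_taxon is not None and tree.is_within(a.best_hit_taxon, node)
        )
        lca = sum(
            1
            for a in assignments
            if a.lca_taxon != NOT_ASSIGNED and tree.is_within(a.lca_taxon, node)
        )
        rows.append(
            {
                "category": name,
                "best_hit_count": best,
                "best_hit_pct": 100.0 * best / n if n else 0.0,
                "lca_count": lca,
                "lca_pct": 100.0 * lca / n if n else 0.0,
            }
        )
    unassigned = sum(1 for a in assignments if a.lca_taxon == NOT_ASSIGNED)
    rows.append(
        {
            "category": "unassigned",
            "best_hit_count": sum(1 for a in assignments if a.best_hit_taxon is None),
            "best_hit_pct": 100.0
            * sum(1 for a in assignments if a.best_hit_taxon is None)
            / n
            if n
            else 0.0,
            "lca_count": unassigned,
            "lca_pct": 100.0 * unassigned / n if n else 0.0,
        }
    )
    return pd.DataFrame(rows)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def plastid_screen(
    hits_by_query: dict[str, list[HitRecord]],
    gene_intervals: list[tuple[int, int]],
    genome_length: int,
    max_span: int = 3500,
    max_genes: int = 5,
) -> dict[str, str]:
    """Flag queries whose plastid hits look like genomic DNA carry-over.

    Subject-coordinate hit intervals (1-based inclusive in the input,
    converted to 0-based half-open internally) are merged per query; a
    query is flagged ``genomic_contamination`` when its merged span
    exceeds ``max_span`` bp (strictly) or the merged region overlaps more
    than ``max_genes`` distinct annotated genes; otherwise
    ``putative_transcript``.
    """
    for s, e in gene_intervals:
        if e > genome_length:
            raise ValueError("gene annotation extends past the genome length")
    flags: dict[str, str] = {}
    for query, hits in sorted(hits_by_query.items()):
        intervals = []
        for h in hits:
            lo, hi = sorted((h.sstart, h.send))
            intervals.append((lo - 1, hi))  # to 0-based half-open
        merged = _merge_intervals(intervals)
        span = max(e - s for s, e in merged)
        genes = set()
        for i, (gs, ge) in enumerate(gene_intervals):
            for s, e in merged:
                if s < ge and gs < e:
                    genes.add(i)
                    break
        if span > max_span or len(genes) > max_genes:
            flags[query] = "genomic_contamination"
        else:
            flags[query] = "putative_transcript"
    return flags


def load_gene_intervals_gff3(path) -> tuple[list[tuple[int, int]], int]:
    """Gene intervals (0-based half-open) and sequence length from a GFF3 file.

    Uses the ``##sequence-region`` pragma for the genome length when
    present; otherwise the maximum annotated end coordinate.
    """
    genes: list[tuple[int, int]] = []
    length = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                length = int(parts[3])
                continue
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            if cols[2] == "gene":
                genes.append((int(cols[3]) - 1, int(cols[4])))
    if length == 0 and genes:
        length = max(e for _, e in genes)
    return sorted(genes), length
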