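"""Self-contained synthetic input bundles for the full pipeline.

Everything downstream of the read simulator also needs side inputs a
sequencing project would normally pull from databases: a taxonomy tree, a
homology-hit table, an ontology with a slim cut, per-sequence GO
annotations, a repeat-consensus library, an annotated plastid genome and
reference gene lists.  The generators here fabricate small, internally
consistent versions of each with known ground truth, deterministic in the
seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import SimulatedRead, TranscriptSet, _random_dna
from .taxonomy_screen import HIT_COLUMNS, TaxonomyTree

__all__ = [
    "toy_taxonomy",
    "plant_category_nodes",
    "simulate_hit_table",
    "toy_ontology_obo",
    "simulate_annotations",
    "repeat_library",
    "plastid_genome",
]


# A miniature, plant-centric taxonomy in the NCBI style: the green-plant
# backbone the screening categories refer to, plus non-plant outgroups
# that contaminant reads map to.  Node ids are stable by construction.
_TAXO_NODES = [
    (1, 1, "no rank", "root"),
    (2, 1, "no rank", "cellular organisms"),
    (10, 2, "superkingdom", "Eukaryota"),
    (20, 2, "superkingdom", "Bacteria"),
    (11, 10, "kingdom", "Viridiplantae"),
    (12, 10, "kingdom", "Fungi"),
    (13, 10, "kingdom", "Metazoa"),
    (30, 11, "phylum", "Chlorophyta"),
    (31, 11, "phylum", "Streptophyta"),
    (40, 31, "clade", "Embryophyta"),
    (41, 40, "clade", "Bryophyta"),
    (42, 40, "clade", "Tracheophyta"),
    (43, 42, "clade", "Lycopodiopsida"),
    (44, 42, "clade", "Polypodiopsida"),
    (45, 42, "clade", "Spermatophyta"),
    (46, 45, "clade", "Acrogymnospermae"),
    (47, 45, "clade", "Magnoliopsida"),
    # species-level leaves hits point at
    (100, 44, "species", "Pteridium aquilinum"),
    (101, 44, "species", "Adiantum capillus-veneris"),
    (102, 43, "species", "Selaginella moellendorffii"),
    (103, 41, "species", "Physcomitrella patens"),
    (104, 47, "species", "Arabidopsis thaliana"),
    (105, 47, "species", "Oryza sativa"),
    (106, 46, "species", "Picea abies"),
    (107, 30, "species", "Chlamydomonas reinhardtii"),
    (200, 20, "species", "Escherichia coli"),
    (201, 12, "species", "Saccharomyces cerevisiae"),
    (202, 13, "species", "Drosophila melanogaster"),
    (203, 13, "species", "Homo sapiens"),
]

_PLANT_SPECIES = [100, 101, 102, 103, 104, 105, 106]
_CONTAM_SPECIES = [200, 201, 202, 203]


def toy_taxonomy() -> TaxonomyTree:
    return TaxonomyTree(_TAXO_NODES)


def plant_category_nodes() -> dict[str, int]:
    """Nested screening categories mirroring a green-plant-focused summary."""
    return {
        "Eukaryotes": 10,
        "Green plants": 11,
        "Land plants": 40,
        "Vascular plants": 42,
        "Ferns": 44,
        "Seed plants": 45,
        "Angiosperms": 47,
        "Bacteria": 20,
        "Animals": 13,
        "Fungi": 12,
    }


def simulate_hit_table(
    queries: list[tuple[str, bool]],
    seed: int,
    hit_prob: float = 0.8,
) -> pd.DataFrame:
    """Fabricate a 13-column homology-hit table consistent with read truth.

    ``queries`` holds (query_id, is_contaminant).  Target-library queries
    draw their hits from plant species taxa; contaminant queries from
    non-plant taxa.  Bitscores decay from a strong top hit so the LCA
    qualification window behaves as it would on real search output.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for query_id, is_contaminant in queries:
        if rng.random() > hit_prob:
            continue
        pool = _CONTAM_SPECIES if is_contaminant else _PLANT_SPECIES
        n_hits = int(rng.integers(3, 9))
        top = float(rng.uniform(120, 400))
        for h in range(n_hits):
            bitscore = top * (1.0 - 0.04 * h) - float(rng.uniform(0, 5))
            taxon = int(pool[rng.integers(len(pool))])
            aln_len = int(rng.integers(40, 200))
            rows.append(
                {
                    "qseqid": query_id,
                    "sseqid": f"sbj{rng.integers(1_000_000):06d}",
                    "pident": round(float(rng.uniform(60, 99)), 2),
                    "length": aln_len,
                    "mismatch": int(rng.integers(0, 30)),
                    "gapopen": int(rng.integers(0, 4)),
                    "qstart": 1,
                    "qend": aln_len,
                    "sstart": 1,
                    "send": aln_len,
                    "evalue": float(10.0 ** -rng.uniform(15, 60)),
                    "bitscore": round(bitscore, 1),
                    "staxids": taxon,
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# ontology


def toy_ontology_obo(path) -> set[str]:
    """Write a miniature GO-like ontology in OBO 1.2; returns the slim ids.

    Three namespaces, each a small DAG whose upper levels form the slim
    cut, with both is_a and part_of edges on the paths up.
    """
    terms = []
    slim = set()

    def term(tid, name, ns, is_a=(), part_of=(), in_slim=False):
        terms.append((tid, name, ns, is_a, part_of, in_slim))
        if in_slim:
            slim.add(tid)

    term("GO:0000001", "biological_process", "biological_process", in_slim=True)
    term("GO:0000010", "metabolic process", "biological_process", ["GO:0000001"], in_slim=True)
    term("GO:0000011", "transport", "biological_process", ["GO:0000001"], in_slim=True)
    term("GO:0000012", "photosynthesis", "biological_process", ["GO:0000010"], in_slim=True)
    term("GO:0000110", "carbon fixation", "biological_process", ["GO:0000012"])
    term("GO:0000111", "glycolysis", "biological_process", ["GO:0000010"])
    term("GO:0000112", "ion transport", "biological_process", ["GO:0000011"])
    term("GO:0000113", "light harvesting", "biological_process", is_a=["GO:0000110"], part_of=["GO:0000012"])

    term("GO:0000002", "cellular_component", "cellular_component", in_slim=True)
    term("GO:0000020", "plastid", "cellular_component", ["GO:0000002"], in_slim=True)
    term("GO:0000021", "ribosome", "cellular_component", ["GO:0000002"], in_slim=True)
    term("GO:0000120", "thylakoid", "cellular_component", is_a=[], part_of=["GO:0000020"])
    term("GO:0000121", "small ribosomal subunit", "cellular_component", is_a=[], part_of=["GO:0000021"])

    term("GO:0000003", "molecular_function", "molecular_function", in_slim=True)
    term("GO:0000030", "binding", "molecular_function", ["GO:0000003"], in_slim=True)
    term("GO:0000031", "kinase activity", "molecular_function", ["GO:0000003"], in_slim=True)
    term("GO:0000130", "ATP binding", "molecular_function", ["GO:0000030"])
    term("GO:0000131", "protein kinase activity", "molecular_function", ["GO:0000031"])

    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n\n")
        for tid, name, ns, is_a, part_of, in_slim in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\nname: {name}\nnamespace: {ns}\n")
            if in_slim:
                fh.write("subset: goslim_toy\n")
            for p in is_a:
                fh.write(f"is_a: {p}\n")
            for p in part_of:
                fh.write(f"relationship: part_of {p}\n")
            fh.write("\n")
    return slim


_LEAF_TERMS = [
    "GO:0000110",
    "GO:0000111",
    "GO:0000112",
    "GO:0000113",
    "GO:0000120",
    "GO:0000121",
    "GO:0000130",
    "GO:0000131",
    "GO:0000012",
    "GO:0000030",
]


def simulate_annotations(
    seq_ids: list[str], seed: int, annotated_fraction: float = 0.6,
    weights: list[float] | None = None,
) -> dict[str, set[str]]:
    """Random per-sequence GO term sets over the toy ontology leaves."""
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        p = np.asarray(weights, dtype=float)
        p = p / p.sum()
    out: dict[str, set[str]] = {}
    for sid in seq_ids:
        if rng.random() > annotated_fraction:
            continue
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(_LEAF_TERMS), size=k, replace=False, p=p)
        out[sid] = {_LEAF_TERMS[int(i)] for i in picks}
    return out


# ---------------------------------------------------------------------------
# repeats and plastid


def plant_features(
    transcripts: TranscriptSet,
    library: list[tuple[str, str, str]],
    seed: int,
    ssr_fraction: float = 0.05,
    repeat_fraction: float = 0.03,
    repeat_divergence: float = 0.10,
) -> tuple[TranscriptSet, int, int]:
    """Insert SSR runs and diverged repeat-element copies into transcripts.

    A fraction of transcripts receives one perfect SSR (random primitive
    2-5 bp motif, 8-15 repeats); another fraction receives a fragment of a
    random library element, each copy independently mutated by
    ``repeat_divergence`` so copies of the same element stay well below
    assembly identity thresholds (no chimeric merging) while remaining
    detectable by the 75 %-identity repeat screen.  Returns the modified
    set and the planted SSR / repeat-copy counts.
    """
    from .repeat_ssr import _is_primitive
    from .synthetic_data import Transcript

    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    out = []
    n_ssr = n_rep = 0
    for t in transcripts:
        seq = t.sequence
        r = rng.random()
        if r < ssr_fraction and len(seq) > 100:
            while True:
                m = int(rng.integers(2, 6))
                motif = "".join(rng.choice(bases, size=m))
                if _is_primitive(motif) and len(set(motif)) > 1:
                    break
            reps = int(rng.integers(8, 16))
            pos = int(rng.integers(30, len(seq) - 30))
            seq = seq[:pos] + motif * reps + seq[pos:]
            n_ssr += 1
        elif r < ssr_fraction + repeat_fraction and len(seq) > 150 and library:
            eid, cls, elem = library[int(rng.integers(len(library)))]
            lo = int(rng.integers(0, max(1, len(elem) - 150)))
            frag = list(elem[lo : lo + int(rng.integers(120, min(300, len(elem) - lo) + 1))])
            for i in range(len(frag)):
                if rng.random() < repeat_divergence:
                    frag[i] = bases[int(rng.integers(4))]
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + "".join(frag) + seq[pos:]
            n_rep += 1
        out.append(Transcript(t.transcript_id, seq, t.true_abundance))
    return TranscriptSet(out), n_ssr, n_rep


def repeat_library(seed: int) -> list[tuple[str, str, str]]:
    """A small labelled repeat-consensus library (element_id, class, sequence)."""
    rng = np.random.default_rng(seed)
    classes = [
        ("copia1", "LTR/Copia", 400),
        ("gypsy1", "LTR/Gypsy", 450),
        ("line1", "LINE/L1", 350),
        ("enspm1", "DNA/En-Spm", 300),
        ("helitron1", "RC/Helitron", 320),
    ]
    return [(eid, cls, _random_dna(rng, n)) for eid, cls, n in classes]


def plastid_genome(
    seed: int, n_genes: int = 40, gene_length: int = 900, spacer: int = 300
) -> tuple[str, list[tuple[int, int]]]:
    """A synthetic plastid genome and its gene intervals (0-based half-open)."""
    rng = np.random.default_rng(seed)
    length = n_genes * (gene_length + spacer) + spacer
    genome = _random_dna(rng, length)
    genes = [
        (spacer + i * (gene_length + spacer), spacer + i * (gene_length + spacer) + gene_length)
        for i in range(n_genes)
    ]
    return genome, genes


def write_gff3(path, genes: list[tuple[int, int]], seq_id: str, length: int) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seq_id} 1 {length}\n")
        for i, (s, e) in enumerate(genes, 1):
            fh.write(
                f"{seq_id}\tsynthetic\tgene\t{s + 1}\t{e}\t.\t+\t.\tID=gene{i:03d}\n"
            )
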