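"""Greedy overlap-layout-consensus assembly of long single-end reads.

Two passes, mirroring the classic two-step EST assembly strategy:

* a primary pass that detects pairwise read overlaps by shared k-mers,
  verifies them with banded alignment, lays reads out greedily per
  connected component (seeding at the most-connected read) and calls a
  per-column majority consensus, retaining unplaced reads as singletons;
* a secondary redundancy-reducing pass that merges the resulting unigene
  sequences (contigs plus singletons) whenever they overlap by at least
  25 bp at >= 95 % identity, labelling merged products as secondary
  contigs and never discarding reads.

Identity is defined as matches divided by alignment columns, counting gap
columns.  All coordinates are 0-based half-open; reverse-complement
placements are fully supported and consensi are reported on the seed
read's strand.
"""

from __future__ import annotations

import heapq
import itertools
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "Overlap",
    "Placement",
    "Unigene",
    "AssemblyResult",
    "find_overlaps",
    "assemble_primary",
    "assemble_secondary",
    "compute_depth",
    "revcomp",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

# k-mers occurring in more reads than this are treated as repeats and not
# used to seed candidate pairs
_MAX_KMER_OCC = 60
_DIAG_BAND = 12


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Overlap:
    """A verified pairwise overlap.

    ``b_interval`` is expressed on read b's forward strand when
    ``orientation`` is '+', and on its reverse complement when '-'.
    """

    read_a: str
    read_b: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    orientation: str  # '+' same strand, '-' reverse complement
    identity: float
    length: int  # alignment columns


@dataclass
class Placement:
    read_id: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class Unigene:
    unigene_id: str
    consensus: str
    category: str  # primary_contig | secondary_contig | singleton
    members: list[Placement] = field(default_factory=list)

    @property
    def depth(self) -> float:
        return compute_depth(self)


@dataclass
class AssemblyResult:
    unigenes: list[Unigene]
    discarded_reads: list[str]
    step_stats: dict

    def category_counts(self) -> dict:
        out = {"primary_contig": 0, "secondary_contig": 0, "singleton": 0}
        for u in self.unigenes:
            out[u.category] += 1
        return out


def compute_depth(unigene: Unigene) -> float:
    """Mean read-depth: summed member placement lengths over consensus length."""
    if not unigene.consensus:
        raise ValueError(f"{unigene.unigene_id}: zero-length consensus")
    return sum(p.end - p.start for p in unigene.members) / len(unigene.consensus)


# ---------------------------------------------------------------------------
# overlap detection


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_values(seq: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    v = np.zeros(n - k + 1, dtype=np.uint64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : n - k + 1 + j]
        v = v * np.uint64(4) + window
        valid &= window < 4
    v[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return v


def _identity_from_cigar(cigar: str, edit_distance: int) -> tuple[float, int, int, int]:
    """(identity, columns, query_consumed, target_consumed) from an extended cigar."""
    matches = columns = q = t = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(num)
        columns += n
        if op in "=XM":
            q += n
            t += n
            if op == "=":
                matches += n
            elif op == "M":
                matches += n  # edlib emits '=' but be tolerant
        elif op == "I":
            q += n
        elif op == "D":
            t += n
    ident = matches / columns if columns else 0.0
    return ident, columns, q, t


def _verify_candidate(
    seq_a: str, seq_b_oriented: str, diag: int, min_overlap: int, min_identity: float
) -> tuple[float, int, tuple[int, int], tuple[int, int]] | None:
    """Align the dovetail overlap implied by a shared-k-mer diagonal."""
    la, lb = len(seq_a), len(seq_b_oriented)
    a0 = max(0, diag)
    b0 = max(0, -diag)
    span = min(la - a0, lb - b0)
    if span < min_overlap:
        return None
    sub_a = seq_a[a0 : a0 + span]
    sub_b = seq_b_oriented[b0 : b0 + span]
    # identity >= min_id forces editDistance <= (1 - min_id) * columns;
    # a generous multiple of that bound lets edlib abandon bad pairs early
    max_dist = int((1.0 - min_identity) * span * 1.6) + 4
    res = edlib.align(sub_a, sub_b, mode="NW", task="path", k=max_dist)
    if res["editDistance"] < 0:
        return None
    ident, columns, qlen, tlen = _identity_from_cigar(res["cigar"], res["editDistance"])
    if columns < min_overlap or ident < min_identity:
        return None
    return ident, columns, (a0, a0 + qlen), (b0, b0 + tlen)


def find_overlaps(
    reads: list[tuple[str, str]],
    k: int = 16,
    min_overlap: int = 40,
    min_identity: float = 0.94,
    index_stride: int = 1,
) -> list[Overlap]:
    """Detect pairwise overlaps via shared k-mers on both strands.

    Candidate pairs share at least one exact k-mer (in either relative
    orientation); each candidate diagonal cluster is verified by global
    alignment of the implied overlap region.  The best overlap per
    unordered read pair is reported once.

    ``index_stride`` subsamples the k-mer index (queries always use every
    position), trading memory for a guarantee floor: overlaps whose
    longest exact stretch is >= k + stride - 1 are still always seeded.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if min_overlap < k:
        raise ValueError("min_overlap must be >= k")
    ids = [rid for rid, _ in reads]
    seqs = [s.upper() for _, s in reads]
    n_reads = len(seqs)

    # strided index over both strands of every read
    ik, ir, ip, istr = [], [], [], []
    for idx, s in enumerate(seqs):
        for strand, ss in ((0, s), (1, revcomp(s))):
            v = _kmer_values(ss, k)
            if len(v) == 0:
                continue
            sel = np.arange(0, len(v), index_stride)
            ik.append(v[sel])
            ir.append(np.full(len(sel), idx, dtype=np.int32))
            ip.append(sel.astype(np.int32))
            istr.append(np.full(len(sel), strand, dtype=np.int8))
    if not ik:
        return []
    ikmer = np.concatenate(ik)
    irid = np.concatenate(ir)
    ipos = np.concatenate(ip)
    istrand = np.concatenate(istr)
    valid = ikmer != np.uint64(0xFFFFFFFFFFFFFFFF)
    ikmer, irid, ipos, istrand = ikmer[valid], irid[valid], ipos[valid], istrand[valid]
    order = np.argsort(ikmer, kind="stable")
    ikmer, irid, ipos, istrand = ikmer[order], irid[order], ipos[order], istrand[order]

    # query every forward k-mer of every read against the index, in chunks
    cand_parts = []
    chunk = 4096
    for lo in range(0, n_reads, chunk):
        qk, qr, qp = [], [], []
        for idx in range(lo, min(lo + chunk, n_reads)):
            v = _kmer_values(seqs[idx], k)
            if len(v) == 0:
                continue
            qk.append(v)
            qr.append(np.full(len(v), idx, dtype=np.int32))
            qp.append(np.arange(len(v), dtype=np.int32))
        if not qk:
            continue
        qkmer = np.concatenate(qk)
        qrid = np.concatenate(qr)
        qpos = np.concatenate(qp)
        valid = qkmer != np.uint64(0xFFFFFFFFFFFFFFFF)
        qkmer, qrid, qpos = qkmer[valid], qrid[valid], qpos[valid]
        left = np.searchsorted(ikmer, qkmer, side="left")
        right = np.searchsorted(ikmer, qkmer, side="right")
        counts = right - left
        counts = np.where(counts > _MAX_KMER_OCC, 0, counts)  # repeat filter
        total = int(counts.sum())
        if total == 0:
            continue
        # expand each query k-mer to its index matches
        qidx = np.repeat(np.arange(len(qkmer)), counts)
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        within = np.arange(total) - offsets
        iidx = np.repeat(left, counts) + within
        ra = qrid[qidx]
        rb = irid[iidx]
        keep = ra < rb  # canonical pair order; the (b,a) instances are duplicates
        if not keep.any():
            continue
        ra = ra[keep]
        rb = rb[keep]
        diag = (qpos[qidx][keep] - ipos[iidx][keep]).astype(np.int32)
        orient = istrand[iidx][keep]
        cand_parts.append(
            np.stack(
                [ra.astype(np.int64), rb.astype(np.int64), orient.astype(np.int64), diag.astype(np.int64)],
                axis=1,
            )
        )
    if not cand_parts:
        return []
    cand = np.concatenate(cand_parts)
    cand = cand[np.lexsort((cand[:, 3], cand[:, 2], cand[:, 1], cand[:, 0]))]
    ra, rb, orient, diag = cand[:, 0], cand[:, 1], cand[:, 2], cand[:, 3]
    pair_key = np.stack([ra, rb, orient], axis=1)
    new_pair = np.ones(len(ra), dtype=bool)
    new_pair[1:] = np.any(pair_key[1:] != pair_key[:-1], axis=1)
    pair_starts = np.flatnonzero(new_pair)
    pair_ends = np.concatenate((pair_starts[1:], [len(ra)]))

    rc_cache: dict[int, str] = {}
    best: dict[tuple[int, int], tuple] = {}
    for s0, e0 in zip(pair_starts, pair_ends):
        a_idx, b_idx, ori = int(ra[s0]), int(rb[s0]), int(orient[s0])
        ds = diag[s0:e0]
        if ori:
            if b_idx not in rc_cache:
                rc_cache[b_idx] = revcomp(seqs[b_idx])
            seq_b = rc_cache[b_idx]
        else:
            seq_b = seqs[b_idx]
        # cluster nearby diagonals; one verification per cluster
        cluster_reps = []
        cstart = 0
        for t in range(1, len(ds) + 1):
            if t == len(ds) or ds[t] - ds[t - 1] > _DIAG_BAND:
                cluster_reps.append(int(np.median(ds[cstart:t])))
                cstart = t
        pair_best = None
        for d in cluster_reps:
            hit = _verify_candidate(
                seqs[a_idx], seq_b, d, min_overlap, min_identity
            )
            if hit is None:
                continue
            ident, columns, aint, bint = hit
            cand = (ident, columns, aint, bint, "-" if ori else "+")
            if pair_best is None or (cand[0], cand[1]) > (pair_best[0], pair_best[1]):
                pair_best = cand
        if pair_best is None:
            continue
        prev = best.get((a_idx, b_idx))
        if prev is None or (pair_best[0], pair_best[1]) > (prev[0], prev[1]):
            best[(a_idx, b_idx)] = pair_best

    out = []
    for (a_idx, b_idx), (ident, columns, aint, bint, ori) in sorted(best.items()):
        out.append(
            Overlap(
                read_a=ids[a_idx],
                read_b=ids[b_idx],
                a_interval=aint,
                b_interval=bint,
                orientation=ori,
                identity=ident,
                length=columns,
            )
        )
    return out


# ---------------------------------------------------------------------------
# layout + consensus


def _place_via_overlap(
    ov: Overlap, anchored_is_a: bool, pos: int, strand: str, len_a: int, len_b: int
) -> tuple[int, str]:
    """Contig offset and strand for the unplaced partner of an overlap."""
    a0, a1 = ov.a_interval
    b0, b1 = ov.b_interval
    if anchored_is_a:
        # b is placed relative to a; coordinates are in the frame
        # "a forward vs oriented b"
        if strand == "+":
            off = pos + (a0 - b0)
            st = "+" if ov.orientation == "+" else "-"
        else:
            # contig sees rc(a): flip the overlap frame
            off = pos + ((len_a - a1) - (len_b - b1))
            st = "-" if ov.orientation == "+" else "+"
    else:
        if strand == "+" and ov.orientation == "+":
            off, st = pos + (b0 - a0), "+"
        elif strand == "+" and ov.orientation == "-":
            # b was laid forward but the overlap frame holds rc(b):
            # flip frame so b appears forward => a appears reverse
            off = pos + ((len_b - b1) - (len_a - a1))
            st = "-"
        elif strand == "-" and ov.orientation == "+":
            off = pos + ((len_b - b1) - (len_a - a1))
            st = "-"
        else:  # b placed '-' and rc overlap => a forward
            off, st = pos + (b0 - a0), "+"
    return off, st


def _consensus(
    order: list[tuple[int, int, str]], seqs: list[str]
) -> tuple[str, list[tuple[int, int, int, str]]]:
    """Majority-vote consensus; ties go to the earliest-placed covering read.

    Returns the consensus string and per-read placements
    (read_index, start, end, strand) on consensus coordinates.
    """
    shift = -min(off for _, off, _ in order)
    placements = []
    for idx, off, strand in order:
        seq = seqs[idx] if strand == "+" else revcomp(seqs[idx])
        placements.append((idx, off + shift, off + shift + len(seq), strand, seq))
    length = max(p[2] for p in placements)
    counts = np.zeros((4, length), dtype=np.int32)
    for _, s0, s1, _, seq in placements:
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        ok = codes < 4
        np.add.at(counts, (codes[ok], np.arange(s0, s1)[ok]), 1)
    winners = counts.argmax(axis=0)
    top = counts.max(axis=0)
    tie_cols = np.flatnonzero((counts == top).sum(axis=0) > 1)
    cons = np.frombuffer(b"ACGT", dtype="S1")[winners].copy()
    if len(tie_cols):
        tie_set = set(tie_cols.tolist())
        for _, s0, s1, _, seq in placements:  # earliest placed first
            if not tie_set:
                break
            for col in [c for c in tie_set if s0 <= c < s1]:
                base = seq[col - s0]
                if counts["ACGT".index(base), col] == top[col]:
                    cons[col] = base.encode()
                    tie_set.discard(col)
    consensus = cons.tobytes().decode()
    return consensus, [(idx, s0, s1, strand) for idx, s0, s1, strand, _ in placements]


def _polish_placements(
    consensus: str,
    placements: list[tuple[int, int, int, str]],
    seqs: list[str],
    min_identity: float,
) -> tuple[list[tuple[int, int, int, str]], list[int]]:
    """Re-anchor each read on the consensus; release reads below min_identity."""
    kept, released = [], []
    for idx, s0, s1, strand in placements:
        seq = seqs[idx] if strand == "+" else revcomp(seqs[idx])
        lo = max(0, s0 - 20)
        hi = min(len(consensus), s1 + 20)
        res = edlib.align(seq, consensus[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        ident = 1.0 - dist / max(1, len(seq))
        if ident < min_identity:
            released.append(idx)
            continue
        loc = res["locations"][0]
        kept.append((idx, lo + loc[0], lo + loc[1] + 1, strand))
    return kept, released


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _assemble(
    reads: list[tuple[str, str]],
    min_identity: float,
    min_overlap: int,
    k: int,
    category: str,
    id_prefix: str,
    index_stride: int | None = None,
) -> tuple[list[Unigene], list[int], dict]:
    """Shared greedy OLC core used by both passes.

    Returns contig unigenes plus the indices of reads left unplaced
    (callers decide what a singleton means for their pass).
    ``index_stride=None`` picks a dense index for small inputs and a
    strided one for large read sets to bound memory.
    """
    if index_stride is None:
        index_stride = 1 if len(reads) < 5000 else 8
    ids = [rid for rid, _ in reads]
    seqs = [s.upper() for _, s in reads]
    overlaps = find_overlaps(
        reads,
        k=k,
        min_overlap=min_overlap,
        min_identity=min_identity,
        index_stride=index_stride,
    )

    index = {rid: i for i, rid in enumerate(ids)}
    uf = _UnionFind(len(reads))
    adj: dict[int, list] = {}
    for ov in overlaps:
        a, b = index[ov.read_a], index[ov.read_b]
        uf.union(a, b)
        adj.setdefault(a, []).append((ov.identity, ov.length, b, ov, True))
        adj.setdefault(b, []).append((ov.identity, ov.length, a, ov, False))

    comps: dict[int, list[int]] = {}
    for i in range(len(reads)):
        comps.setdefault(uf.find(i), []).append(i)

    contigs: list[Unigene] = []
    loose: list[int] = []
    serial = 0
    for root in sorted(comps):
        comp = comps[root]
        if len(comp) == 1:
            loose.append(comp[0])
            continue
        order = _layout_full(comp, adj, seqs)
        consensus, placements = _consensus(order, seqs)
        placements, released = _polish_placements(consensus, placements, seqs, min_identity)
        loose.extend(released)
        if len(placements) < 2:
            loose.extend(idx for idx, *_ in placements)
            continue
        if released:
            retained = [
                (idx, s0, "+" if st == "+" else "-")
                for idx, s0, s1, st in placements
            ]
            consensus, placements = _consensus(
                [(idx, s0, st) for idx, s0, st in retained], seqs
            )
        serial += 1
        contigs.append(
            Unigene(
                unigene_id=f"{id_prefix}{serial:06d}",
                consensus=consensus,
                category=category,
                members=[
                    Placement(ids[idx], s0, s1, st) for idx, s0, s1, st in placements
                ],
            )
        )
    return contigs, loose, {"n_overlaps": len(overlaps)}


def _layout_full(comp, adj, seqs):
    """Greedy placement of one connected component.

    Returns (read_index, offset, strand) in placement order.  The seed is
    the most-connected read (ties by index); extension always follows the
    best remaining overlap (identity, then length) from a placed read to
    an unplaced one.
    """
    fixed = []
    placed: dict[int, tuple[int, str]] = {}
    heap = []
    counter = itertools.count()
    seed = max(comp, key=lambda i: (len(adj.get(i, [])), -i))
    placed[seed] = (0, "+")
    fixed.append((seed, 0, "+"))

    def push(i):
        for ident, length, other, ov, i_is_a in adj.get(i, []):
            heapq.heappush(
                heap, (-ident, -length, next(counter), i, other, ov, i_is_a)
            )

    push(seed)
    while heap:
        negident, neglen, _, i, other, ov, i_is_a = heapq.heappop(heap)
        if other in placed or i not in placed:
            continue
        pos_i, strand_i = placed[i]
        a_idx = i if i_is_a else other
        b_idx = other if i_is_a else i
        off, st = _place_via_overlap(
            ov, i_is_a, pos_i, strand_i, len(seqs[a_idx]), len(seqs[b_idx])
        )
        placed[other] = (off, st)
        fixed.append((other, off, st))
        push(other)
    return fixed


def assemble_primary(
    reads: list[tuple[str, str]],
    min_identity: float = 0.94,
    min_overlap: int = 40,
    k: int = 16,
) -> AssemblyResult:
    """Primary greedy OLC pass; unplaced reads are retained as singletons."""
    contigs, loose, info = _assemble(
        reads, min_identity, min_overlap, k, "primary_contig", "PC"
    )
    unigenes = list(contigs)
    seq_of = dict(reads)
    for n, idx in enumerate(sorted(loose), 1):
        rid = reads[idx][0]
        unigenes.append(
            Unigene(
                unigene_id=f"SG{n:06d}",
                consensus=seq_of[rid].upper(),
                category="singleton",
                members=[Placement(rid, 0, len(seq_of[rid]), "+")],
            )
        )
    n_assembled = sum(len(u.members) for u in contigs)
    stats = {
        "reads_in": len(reads),
        "reads_assembled": n_assembled,
        "reads_discarded": 0,
        "singletons": len(loose),
        "primary_contigs": len(contigs),
        "secondary_contigs": 0,
        "unigenes": len(unigenes),
    }
    return AssemblyResult(unigenes=unigenes, discarded_reads=[], step_stats={"primary": stats})


def assemble_secondary(
    primary: AssemblyResult,
    min_identity: float = 0.95,
    min_overlap: int = 25,
    k: int = 12,
) -> AssemblyResult:
    """Merge redundant unigenes (>= min_overlap bp at >= min_identity).

    Member reads of merged unigenes are unioned onto the merged consensus;
    no reads are ever discarded in this step and the unigene count never
    increases.
    """
    inputs = primary.unigenes
    useqs = [(u.unigene_id, u.consensus) for u in inputs]
    by_id = {u.unigene_id: u for u in inputs}
    contigs, loose, _ = _assemble(
        useqs, min_identity, min_overlap, k, "secondary_contig", "SC"
    )

    unigenes: list[Unigene] = []
    for merged in contigs:
        members: list[Placement] = []
        for placement in merged.members:
            src = by_id[placement.read_id]
            ulen = len(src.consensus)
            for m in src.members:
                if placement.strand == "+":
                    members.append(
                        Placement(
                            m.read_id,
                            placement.start + m.start,
                            placement.start + m.end,
                            m.strand,
                        )
                    )
                else:
                    flipped = "-" if m.strand == "+" else "+"
                    members.append(
                        Placement(
                            m.read_id,
                            placement.start + (ulen - m.end),
                            placement.start + (ulen - m.start),
                            flipped,
                        )
                    )
        merged.members = sorted(members, key=lambda p: (p.start, p.read_id))
        unigenes.append(merged)
    for idx in sorted(loose):
        unigenes.append(inputs[idx])

    reads_assembled = sum(
        len(u.members) for u in unigenes if u.category != "singleton"
    )
    n_singletons = sum(1 for u in unigenes if u.category == "singleton")
    stats = {
        "reads_in": primary.step_stats["primary"]["reads_in"],
        "reads_assembled": reads_assembled,
        "reads_discarded": 0,
        "singletons": n_singletons,
        "primary_contigs": sum(1 for u in unigenes if u.category == "primary_contig"),
        "secondary_contigs": sum(
            1 for u in unigenes if u.category == "secondary_contig"
        ),
        "unigenes": len(unigenes),
    }
    step_stats = dict(primary.step_stats)
    step_stats["secondary"] = stats
    return AssemblyResult(
        unigenes=unigenes,
        discarded_reads=list(primary.discarded_reads),
        step_stats=step_stats,
    )
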