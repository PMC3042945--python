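"""Microsatellite (SSR) mining and repeat-library screening.

SSR discovery reports maximal perfect tandem repeats of 2-5 bp motifs at
per-motif-length minimum repeat counts (defaults 10/9/7/6 for di- through
pentanucleotides).  Motifs are canonicalized to the lexicographically
minimal string among all rotations of the motif and of its reverse
complement, so equivalent repeats called on either strand or at any phase
collapse to one representative; motifs that are themselves repetitions of
a shorter unit (including homopolymers) are excluded.

Repeat-library screening locally aligns labelled consensus elements
against both strands of the target sequences (match +1, mismatch -2,
gap -3), merges masked intervals per repeat class, and summarizes element
counts, masked length and masked percentage per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .assembly import revcomp

__all__ = [
    "SSRLocus",
    "RepeatMatch",
    "find_ssrs",
    "flank_check",
    "canonical_motif",
    "screen_repeat_library",
    "repeat_summary",
]

DEFAULT_MIN_REPEATS = {2: 10, 3: 9, 4: 7, 5: 6}


@dataclass
class SSRLocus:
    seq_id: str
    motif: str
    n_repeats: int
    interval: tuple[int, int]  # 0-based half-open
    left_flank: int
    right_flank: int
    amplifiable: bool = False


@dataclass
class RepeatMatch:
    seq_id: str
    library_element_id: str
    repeat_class: str
    interval: tuple[int, int]
    identity: float


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation among the motif and its reverse complement."""
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def find_ssrs(
    sequence: str,
    seq_id: str = "",
    min_repeats: dict[int, int] | None = None,
) -> list[SSRLocus]:
    """Maximal perfect SSRs of motif length 2-5 meeting per-length thresholds.

    Overlapping calls at different motif lengths are resolved to the
    longest interval; interval-length ties go to the shorter motif.
    Non-primitive motifs (e.g. ATAT, or homopolymers) are never reported
    as such — the primitive unit's run is what gets called.
    """
    min_repeats = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    for m, r in min_repeats.items():
        if r < 2:
            raise ValueError(f"min repeat count for motif length {m} must be >= 2")
    sequence = sequence.upper()
    n = len(sequence)
    raw: list[tuple[int, int, str, int]] = []  # (start, end, motif, n_repeats)
    for m in sorted(min_repeats):
        for i in range(n - m + 1):
            motif = sequence[i : i + m]
            if not _is_primitive(motif):
                continue
            if i >= m and sequence[i - m : i] == motif:
                continue  # left-extendable: not the maximal run start
            j = i + m
            while j + m <= n and sequence[j : j + m] == motif:
                j += m
            reps = (j - i) // m
            if reps >= min_repeats[m]:
                raw.append((i, j, motif, reps))
    # resolve overlaps across motif lengths: longest interval wins, tie => shorter motif
    raw.sort(key=lambda r: (-(r[1] - r[0]), len(r[2]), r[0]))
    chosen: list[tuple[int, int, str, int]] = []
    for start, end, motif, reps in raw:
        if any(start < c_end and c_start < end for c_start, c_end, _, _ in chosen):
            continue
        chosen.append((start, end, motif, reps))
    chosen.sort()
    return [
        SSRLocus(
            seq_id=seq_id,
            motif=canonical_motif(motif),
            n_repeats=reps,
            interval=(start, end),
            left_flank=start,
            right_flank=n - end,
        )
        for start, end, motif, reps in chosen
    ]


def flank_check(locus: SSRLocus, min_flank: int = 20) -> bool:
    """A locus is potentially amplifiable when both flanks are >= min_flank bp."""
    locus.amplifiable = (
        locus.left_flank >= min_flank and locus.right_flank >= min_flank
    )
    return locus.amplifiable


def ssr_table(loci: list[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [x.seq_id for x in loci],
            "motif": [x.motif for x in loci],
            "n_repeats": [x.n_repeats for x in loci],
            "start": [x.interval[0] for x in loci],
            "end": [x.interval[1] for x in loci],
            "left_flank": [x.left_flank for x in loci],
            "right_flank": [x.right_flank for x in loci],
            "amplifiable": [x.amplifiable for x in loci],
        }
    )


# ---------------------------------------------------------------------------
# repeat-library screening


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -3
    al.extend_gap_score = -3
    return al


def _alignment_identity(alignment) -> tuple[float, int, tuple[int, int]]:
    """(identity, columns, target_interval) of a local alignment."""
    matches = columns = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        seg_t = alignment.target[t0:t1]
        seg_q = alignment.query[q0:q1]
        matches += sum(1 for a, b in zip(seg_t, seg_q) if a == b)
        columns += t1 - t0
    # count gap columns between aligned blocks
    blocks_t = alignment.aligned[0]
    blocks_q = alignment.aligned[1]
    for i in range(1, len(blocks_t)):
        columns += (blocks_t[i][0] - blocks_t[i - 1][1]) + (
            blocks_q[i][0] - blocks_q[i - 1][1]
        )
    t_lo = int(blocks_t[0][0])
    t_hi = int(blocks_t[-1][1])
    ident = matches / columns if columns else 0.0
    return ident, columns, (t_lo, t_hi)


def screen_repeat_library(
    sequences: list[tuple[str, str]],
    library: list[tuple[str, str, str]],
    min_identity: float = 0.75,
    min_len: int = 30,
) -> list[RepeatMatch]:
    """Local-align library elements against both strands of each sequence.

    ``library`` rows are (element_id, repeat_class, consensus sequence).
    Matches shorter than ``min_len`` alignment columns or below
    ``min_identity`` are dropped.  Within one (sequence, element, strand)
    combination, matched regions are masked and the search repeated, so
    multiple copies of an element are all reported.
    """
    for element_id, repeat_class, _ in library:
        if not repeat_class:
            raise ValueError(f"library element {element_id} has no class label")
    aligner = _aligner()
    matches: list[RepeatMatch] = []
    for seq_id, seq in sequences:
        seq = seq.upper()
        for element_id, repeat_class, consensus in library:
            for strand, elem in (("+", consensus.upper()), ("-", revcomp(consensus.upper()))):
                target = seq
                while True:
                    if not target or not elem:
                        break
                    alns = aligner.align(target, elem)
                    if len(alns) == 0 or alns.score <= 0:
                        break
                    ident, columns, (lo, hi) = _alignment_identity(alns[0])
                    if columns < min_len or ident < min_identity:
                        break
                    matches.append(
                        RepeatMatch(
                            seq_id=seq_id,
                            library_element_id=element_id,
                            repeat_class=repeat_class,
                            interval=(lo, hi),
                            identity=ident,
                        )
                    )
                    target = target[:lo] + "N" * (hi - lo) + target[hi:]
    return matches


def repeat_summary(
    matches: list[RepeatMatch], sequences: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-class element counts, merged masked length and masked percentage."""
    total_bp = sum(len(s) for _, s in sequences)
    by_class: dict[str, list[RepeatMatch]] = {}
    for m in matches:
        by_class.setdefault(m.repeat_class, []).append(m)
    rows = []
    for repeat_class in sorted(by_class):
        ms = by_class[repeat_class]
        masked = 0
        by_seq: dict[str, list[tuple[int, int]]] = {}
        for m in ms:
            by_seq.setdefault(m.seq_id, []).append(m.interval)
        for intervals in by_seq.values():
            merged: list[list[int]] = []
            for s, e in sorted(intervals):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            masked += sum(e - s for s, e in merged)
        rows.append(
            {
                "repeat_class": repeat_class,
                "n_elements": len(ms),
                "total_length": masked,
                "pct_of_sequence": 100.0 * masked / total_bp if total_bp else 0.0,
            }
        )
    return pd.DataFrame(rows)
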