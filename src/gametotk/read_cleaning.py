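"""Adapter, polyA/T and length filtering of raw long reads.

Cleaning proceeds per read in a fixed order: adapter trimming (terminal
matches with a bounded mismatch rate; full internal matches truncate the
read), aggressive sliding-window polyA/T trimming from both ends, then a
length filter.  The report reconciles read and base counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CleanRead",
    "CleaningReport",
    "CleaningConfig",
    "trim_adapter",
    "trim_polyAT",
    "clean_reads",
]


@dataclass
class CleanRead:
    read_id: str
    sequence: str
    trim_log: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class CleaningReport:
    n_in: int = 0
    n_out: int = 0
    n_discarded_short: int = 0
    total_bp_in: int = 0
    total_bp_out: int = 0

    @property
    def bp_removed(self) -> int:
        return self.total_bp_in - self.total_bp_out

    def validate(self) -> None:
        if self.n_in != self.n_out + self.n_discarded_short:
            raise ValueError("cleaning report does not reconcile read counts")
        if self.total_bp_out > self.total_bp_in:
            raise ValueError("cleaning cannot add bases")


@dataclass
class CleaningConfig:
    adapters: tuple[str, ...] = ()
    max_mismatch_rate: float = 0.15
    min_adapter_match: int = 8
    window: int = 10
    min_frac: float = 0.8
    min_run: int = 5
    min_len: int = 78
    max_len: int | None = None


def _count_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapter(
    sequence: str,
    adapter: str,
    max_mismatch_rate: float = 0.15,
    min_match: int = 8,
) -> tuple[str, int]:
    """Remove adapter matches from a read; returns (trimmed, bp_removed).

    All alignments of the adapter against the read are scanned.  An
    alignment touching the read's 5' end trims the prefix through its end;
    one touching the 3' end trims from its start; a full internal match
    truncates the read at the match (keeping the 5' portion).  Partial
    terminal matches must cover at least ``min_match`` bases and carry a
    mismatch fraction <= ``max_mismatch_rate``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not sequence:
        return sequence, 0
    la, lr = len(adapter), len(sequence)
    removed_total = 0

    # full internal match: truncate at the leftmost occurrence
    for start in range(lr - la + 1):
        seg = sequence[start : start + la]
        if _count_mismatches(seg, adapter) <= int(max_mismatch_rate * la):
            if start == 0:
                # equivalent to a prefix trim; handled below uniformly
                break
            removed_total += lr - start
            sequence = sequence[:start]
            lr = len(sequence)
            break

    # prefix: adapter suffix aligned to read start; choose the longest valid
    best = 0
    for ov in range(min(la, lr), min_match - 1, -1):
        if _count_mismatches(sequence[:ov], adapter[la - ov :]) <= int(
            max_mismatch_rate * ov
        ):
            best = ov
            break
    if best:
        sequence = sequence[best:]
        removed_total += best
        lr = len(sequence)

    # suffix: adapter prefix aligned to read end
    best = 0
    for ov in range(min(la, lr), min_match - 1, -1):
        if _count_mismatches(sequence[lr - ov :], adapter[:ov]) <= int(
            max_mismatch_rate * ov
        ):
            best = ov
            break
    if best:
        sequence = sequence[: lr - best]
        removed_total += best

    return sequence, removed_total


def _sweep_end(sequence: str, base: str, window: int, min_frac: float, from_start: bool) -> int:
    """Bases to trim from one end by the sliding-window sweep.

    Windows of ``window`` bases slide inward one base at a time starting
    from the terminal window; while each consecutive window has a
    ``base``-fraction >= ``min_frac``, the chain extends.  The cut reaches
    to the inner edge of the innermost passing window (nothing is trimmed
    if the terminal window itself fails).
    """
    n = len(sequence)
    if n == 0:
        return 0
    w = min(window, n)
    j = 0
    while True:
        if from_start:
            win = sequence[j : j + w]
        else:
            win = sequence[n - j - w : n - j] if n - j - w >= 0 else ""
        if len(win) < w or win.count(base) / w < min_frac:
            break
        j += 1
    if j == 0:
        return 0
    cut = min(n, (j - 1) + w)
    # the innermost window may overhang the tail; give back inner-edge
    # characters that are not the tail base
    if from_start:
        while cut > 0 and sequence[cut - 1] != base:
            cut -= 1
    else:
        while cut > 0 and sequence[n - cut] != base:
            cut -= 1
    return cut


def _strip_pure_run(sequence: str, base: str, min_run: int, from_start: bool) -> int:
    n = 0
    it = sequence if from_start else reversed(sequence)
    for ch in it:
        if ch == base:
            n += 1
        else:
            break
    return n if n >= min_run else 0


def trim_polyAT(
    sequence: str,
    window: int = 10,
    min_frac: float = 0.8,
    min_run: int = 5,
) -> tuple[str, int]:
    """Aggressively trim polyA/polyT stretches from both read ends.

    From each end, windows of ``window`` bases whose A-fraction (or
    T-fraction) is >= ``min_frac`` are trimmed inward one base at a time
    until a window fails; terminal pure runs of length >= ``min_run`` are
    also removed.  Repeats until no further change (composite A/T tails).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0.5 < min_frac <= 1.0:
        raise ValueError("min_frac must lie in (0.5, 1]")
    removed = 0
    changed = True
    while changed and sequence:
        changed = False
        for base in "AT":
            for from_start in (True, False):
                cut = _sweep_end(sequence, base, window, min_frac, from_start)
                if cut:
                    # the sweep engaged: also strip the residual terminal
                    # run of the same base, whatever its length
                    rest = sequence[cut:] if from_start else sequence[: len(sequence) - cut]
                    cut += _strip_pure_run(rest, base, 1, from_start)
                else:
                    cut = _strip_pure_run(sequence, base, min_run, from_start)
                if cut:
                    sequence = sequence[cut:] if from_start else sequence[: len(sequence) - cut]
                    removed += cut
                    changed = True
    return sequence, removed


def clean_reads(
    reads: Iterable[tuple[str, str]] | Sequence,
    config: CleaningConfig | None = None,
) -> tuple[list[CleanRead], CleaningReport]:
    """Apply adapter, polyA/T and length filtering to a read set.

    ``reads`` is an iterable of (read_id, sequence).  Reads falling below
    ``min_len`` (or above ``max_len``, when set) after trimming are
    discarded and counted in the report.
    """
    config = config or CleaningConfig()
    if config.min_len < 1:
        raise ValueError("min_len must be >= 1")
    report = CleaningReport()
    out: list[CleanRead] = []
    for read_id, seq in reads:
        seq = seq.upper()
        report.n_in += 1
        report.total_bp_in += len(seq)
        log: list[tuple[str, int]] = []
        for adapter in config.adapters:
            seq, removed = trim_adapter(
                seq, adapter.upper(), config.max_mismatch_rate, config.min_adapter_match
            )
            if removed:
                log.append(("adapter", removed))
        seq, removed = trim_polyAT(seq, config.window, config.min_frac, config.min_run)
        if removed:
            log.append(("polyAT", removed))
        too_short = len(seq) < config.min_len
        too_long = config.max_len is not None and len(seq) > config.max_len
        if too_short or too_long:
            report.n_discarded_short += 1
            continue
        report.n_out += 1
        report.total_bp_out += len(seq)
        out.append(CleanRead(read_id=read_id, sequence=seq, trim_log=log))
    report.validate()
    return out, report
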