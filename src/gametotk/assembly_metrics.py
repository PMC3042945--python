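"""Sequence-set summary statistics and the bootstrapped unigene accumulation curve.

The accumulation (rarefaction) curve resamples the empirical distribution
of reads per unigene: each bootstrap replicate shuffles the full multiset
of reads, scans them one at a time, and tracks the number of distinct
unigenes detected after every draw.  The mean curve, a percentile
confidence band, milestone draw counts (first draw reaching 90/95/99 % of
the unigene total on the mean curve), and the average number of reads
needed to detect each of the last ten unigenes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LengthStats",
    "AccumulationCurve",
    "length_stats",
    "assembly_report",
    "accumulation_curve",
    "histogram",
]


@dataclass
class LengthStats:
    n: int
    mean: float | None
    sd: float | None
    mode: int | None
    median: float | None
    min: int | None
    max: int | None
    total: int


def length_stats(sequences) -> LengthStats:
    """Eight summary statistics over sequence lengths (or raw lengths).

    ``sequences`` may be an iterable of strings, of (id, sequence) pairs,
    or of integer lengths.  The mode is the smallest length attaining the
    maximal frequency; sd is the population-corrected (ddof=1) standard
    deviation, undefined for n < 2.
    """
    lengths = []
    for item in sequences:
        if isinstance(item, int):
            lengths.append(item)
        elif isinstance(item, str):
            lengths.append(len(item))
        else:
            lengths.append(len(item[1]))
    n = len(lengths)
    if n == 0:
        return LengthStats(0, None, None, None, None, None, None, 0)
    arr = np.array(lengths)
    values, counts = np.unique(arr, return_counts=True)
    mode = int(values[np.argmax(counts)])  # np.unique sorts => smallest wins ties
    return LengthStats(
        n=n,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n > 1 else None,
        mode=mode,
        median=float(np.median(arr)),
        min=int(arr.min()),
        max=int(arr.max()),
        total=int(arr.sum()),
    )


_REPORT_ROWS = [
    "reads_assembled_into_contigs",
    "reads_discarded",
    "reads_retained_as_singletons",
    "primary_contigs",
    "secondary_contigs",
    "total_unigenes",
    "mean_unigene_length",
    "largest_unigene_length",
    "total_assembly_length",
    "mean_read_depth",
]


def assembly_report(result) -> pd.DataFrame:
    """Per-pass assembly summary table.

    One column per completed pass; rows mirror the standard assembly
    summary (reads assembled / discarded / singletons, contig counts,
    unigene count, length statistics, mean depth).  The read-conservation
    identity (assembled + singletons + discarded = input reads) is
    asserted for every pass; a violation means a corrupt assembly.
    """
    columns = {}
    for pass_name, stats in result.step_stats.items():
        assembled = stats["reads_assembled"]
        discarded = stats["reads_discarded"]
        singles = stats["singletons"]
        if assembled + discarded + singles != stats["reads_in"]:
            raise ValueError(
                f"{pass_name} pass violates read conservation: "
                f"{assembled} + {discarded} + {singles} != {stats['reads_in']}"
            )
        if pass_name == list(result.step_stats)[-1]:
            lengths = [len(u.consensus) for u in result.unigenes]
            depths = [u.depth for u in result.unigenes]
        else:
            lengths, depths = [], []
        ls = length_stats(lengths)
        columns[pass_name] = {
            "reads_assembled_into_contigs": assembled,
            "reads_discarded": discarded,
            "reads_retained_as_singletons": singles,
            "primary_contigs": stats["primary_contigs"],
            "secondary_contigs": stats["secondary_contigs"],
            "total_unigenes": stats["unigenes"],
            "mean_unigene_length": ls.mean,
            "largest_unigene_length": ls.max,
            "total_assembly_length": ls.total,
            "mean_read_depth": float(np.mean(depths)) if depths else None,
        }
    return pd.DataFrame(columns).reindex(_REPORT_ROWS)


def reconcile_counts(assembled: int, discarded: int, singletons: int, reads_in: int) -> bool:
    """The read-conservation identity every valid pass must satisfy."""
    return assembled + discarded + singletons == reads_in


@dataclass
class AccumulationCurve:
    mean_detected: np.ndarray  # index t-1 => after t draws
    ci_low: np.ndarray
    ci_high: np.ndarray
    milestones: dict[float, int]
    last10_mean_reads: float | None
    n_boot: int
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.mean_detected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(1, self.n_draws + 1),
                "mean_detected": self.mean_detected,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def accumulation_curve(
    reads_per_unigene,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
    milestone_fractions: tuple[float, ...] = (0.90, 0.95, 0.99),
) -> AccumulationCurve:
    """Bootstrap the unigene accumulation curve from a reads-per-unigene table.

    Each replicate shuffles the labelled read multiset and records the
    cumulative count of distinct unigenes at every draw.  The confidence
    band is the per-draw percentile interval across replicates.  The
    last-ten statistic is computed per replicate — (draw of the Uth
    detection − draw of the (U−10)th) / 10 — then averaged; it is None
    for fewer than 11 unigenes.
    """
    counts = np.asarray(list(reads_per_unigene), dtype=np.int64)
    if len(counts) == 0:
        raise ValueError("empty reads-per-unigene table")
    if (counts < 1).any():
        raise ValueError("every unigene must have at least one read")
    u = len(counts)
    total = int(counts.sum())
    labels = np.repeat(np.arange(u), counts)
    rng = np.random.default_rng(seed)

    detected = np.empty((n_boot, total), dtype=np.int32)
    last10 = np.empty(n_boot) if u >= 11 else None
    for b in range(n_boot):
        perm = rng.permutation(labels)
        # first occurrence index of each label in the shuffled order
        first_idx = np.empty(u, dtype=np.int64)
        first_idx[perm[::-1]] = np.arange(total - 1, -1, -1)
        firsts = np.zeros(total, dtype=bool)
        firsts[first_idx] = True
        detected[b] = np.cumsum(firsts)
        if last10 is not None:
            order = np.sort(first_idx)
            last10[b] = (order[-1] - order[-11]) / 10.0

    mean_detected = detected.mean(axis=0)
    alpha = (1.0 - ci) / 2.0
    ci_low = np.quantile(detected, alpha, axis=0)
    ci_high = np.quantile(detected, 1.0 - alpha, axis=0)
    milestones = {}
    for f in milestone_fractions:
        hit = np.flatnonzero(mean_detected >= f * u)
        milestones[f] = int(hit[0] + 1) if len(hit) else total
    return AccumulationCurve(
        mean_detected=mean_detected,
        ci_low=ci_low,
        ci_high=ci_high,
        milestones=milestones,
        last10_mean_reads=float(last10.mean()) if last10 is not None else None,
        n_boot=n_boot,
        seed=seed,
    )


def expected_accumulation(reads_per_unigene, t: int) -> float:
    """Closed-form without-replacement expectation of unigenes detected at draw t.

    E[detected] = sum_i (1 - C(T - m_i, t) / C(T, t)) for unigene read
    counts m_i summing to T.  Used as an independent check on the
    bootstrap estimator.
    """
    from scipy.special import gammaln

    counts = np.asarray(list(reads_per_unigene), dtype=np.int64)
    total = int(counts.sum())

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for m in counts:
        if total - m < t:
            out += 1.0
        else:
            out += 1.0 - np.exp(log_comb(total - m, t) - log_comb(total, t))
    return float(out)


def histogram(values, bin_width: float, clip: tuple[float, float] | None = None):
    """Half-open fixed-width binning [k*w, (k+1)*w); optional tail pooling.

    When ``clip=(lo, hi)`` is given, all values in [lo, hi) are pooled
    into a single bin keyed by (lo, hi).  Returns a dict mapping
    (bin_start, bin_end) -> count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    out: dict[tuple[float, float], int] = {}
    for v in values:
        if clip is not None and clip[0] <= v < clip[1]:
            key = (float(clip[0]), float(clip[1]))
        else:
            k = int(np.floor(v / bin_width))
            key = (k * bin_width, (k + 1) * bin_width)
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))
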