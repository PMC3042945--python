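"""Synthetic normalized cDNA libraries with known ground truth.

Emulates a long-read (454-style) single-end sequencing run over an unknown
gametophyte transcriptome: a heavy-tailed transcript abundance distribution
flattened by imperfect cDNA normalization, reads of ~372.6 bp mean length
decorated with leftover adapters, polyA/polyT tails, substitution errors and
homopolymer indels, plus an optional spike of contaminant reads from a
foreign library.  Every read carries its source interval and the exact list
of decorations applied, so downstream cleaning and assembly can be scored
against truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Transcript",
    "TranscriptSet",
    "SimulatedRead",
    "SimConfig",
    "simulate_transcriptome",
    "simulate_reads",
    "spike_contaminants",
    "write_fasta",
    "write_fastq",
    "write_truth_table",
    "read_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_DNA = set("ACGT")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    sequence: str
    true_abundance: float


class TranscriptSet:
    """An ordered collection of transcripts with normalized abundances.

    Abundances are renormalized to sum to 1 at construction; ids must be
    unique and sequences non-empty over {A,C,G,T}.
    """

    def __init__(self, records: Iterable[Transcript]):
        records = list(records)
        ids = [r.transcript_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")
        for r in records:
            if not r.sequence or set(r.sequence) - _DNA:
                raise ValueError(f"{r.transcript_id}: sequence must be non-empty over ACGT")
            if r.true_abundance <= 0:
                raise ValueError(f"{r.transcript_id}: abundance must be positive")
        total = sum(r.true_abundance for r in records)
        if records and total > 0:
            records = [
                dataclasses.replace(r, true_abundance=r.true_abundance / total)
                for r in records
            ]
        self.records: list[Transcript] = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]

    def abundances(self) -> np.ndarray:
        return np.array([r.true_abundance for r in self.records], dtype=float)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    source_id: str
    source_interval: tuple[int, int]  # 0-based half-open on the source
    is_contaminant: bool = False
    decorations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def is_error_free(self) -> bool:
        return not any(
            kind in ("substitutions", "homopolymer_indels") and n > 0
            for kind, n in self.decorations
        )


@dataclass
class SimConfig:
    """Parameters of the simulated normalized 454-style library.

    Defaults mirror the cleaned-read statistics of the target platform
    (mean read length 372.60 bp, sd 96.36 bp, observed range 78-624 bp)
    and a normalized library in which the underlying log-normal expression
    skew has been largely, but imperfectly, flattened.

    normalization_exponent is applied as abundance**exponent followed by
    renormalization: 0 gives a perfectly uniform (ideal normalization)
    library, 1 leaves the raw skew untouched.
    """

    n_genes: int = 2000
    length_mean: float = 1500.0  # transcript length law (log-normal), bp
    length_sd: float = 800.0
    min_transcript_length: int = 200
    abundance_sigma: float = 1.5  # log-normal expression skew (log-space sd)
    n_reads: int = 50_000
    read_length_mean: float = 372.6
    read_length_sd: float = 96.36
    read_length_min: int = 78
    read_length_max: int = 624
    normalization_exponent: float = 0.25
    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.002
    adapter_5p: str = "GTTTCCCAGTCACGATA"
    adapter_3p: str = "TATCGTGACTGGGAAAC"
    adapter_5p_prob: float = 0.15
    adapter_3p_prob: float = 0.15
    polyA_prob: float = 0.20
    polyA_mean: float = 18.0
    polyA_sd: float = 6.0
    contaminant_fraction: float = 0.018
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "substitution_rate",
            "homopolymer_indel_rate",
            "adapter_5p_prob",
            "adapter_3p_prob",
            "polyA_prob",
            "contaminant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.normalization_exponent <= 1.0:
            raise ValueError("normalization_exponent must lie in [0, 1]")
        if self.n_reads < 0 or self.n_genes < 0:
            raise ValueError("n_reads and n_genes must be non-negative")
        if self.length_mean <= 0:
            raise ValueError("length_mean must be positive")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a target bp-scale mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_transcriptome(config: SimConfig) -> TranscriptSet:
    """Draw a transcript set with log-normal lengths and abundance skew.

    Lengths are log-normal (moment-matched to ``length_mean``/``length_sd``)
    truncated below at ``min_transcript_length``; abundances are log-normal
    with log-space sd ``abundance_sigma`` and renormalized to sum to 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu, sigma = _lognormal_params(config.length_mean, config.length_sd)
    records = []
    for i in range(config.n_genes):
        length = 0
        while length < config.min_transcript_length:
            length = int(round(rng.lognormal(mu, sigma)))
        seq = _random_dna(rng, length)
        abundance = float(rng.lognormal(0.0, config.abundance_sigma))
        records.append(Transcript(f"tx{i:05d}", seq, abundance))
    return TranscriptSet(records)


def _apply_substitutions(seq: list[str], rate: float, rng: np.random.Generator) -> int:
    n = 0
    if rate <= 0:
        return 0
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        old = seq[i]
        choices = [b for b in "ACGT" if b != old]
        seq[i] = choices[rng.integers(len(choices))]
        n += 1
    return n


def _apply_homopolymer_indels(seq: list[str], rate: float, rng: np.random.Generator) -> int:
    """±1 bp indels in homopolymer runs of length >= 3, the dominant 454 error mode."""
    if rate <= 0 or not seq:
        return 0
    n = 0
    out: list[str] = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate * (j - i):
            if rng.random() < 0.5:
                run = run + [seq[i]]
            else:
                run = run[:-1]
            n += 1
        out.extend(run)
        i = j
    seq[:] = out
    return n


_MIN_TAIL = 6


def _decorate(
    core: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]], int, int]:
    """Apply sequencing artifacts to an error-free fragment.

    Returns (sequence, decorations, absorbed_left, absorbed_right).  A
    polyA/polyT tail absorbs any adjacent identical core bases — the
    core/tail boundary is otherwise unobservable — so the caller must
    shrink the truth interval by the absorbed counts.
    """
    decorations: list[tuple[str, int]] = []
    absorbed_left = absorbed_right = 0

    prefix = ""
    suffix = ""
    if config.polyA_prob > 0 and rng.random() < config.polyA_prob:
        tail_len = max(_MIN_TAIL, int(round(rng.normal(config.polyA_mean, config.polyA_sd))))
        # cDNA fragments read from the antisense strand show the tail as 5' polyT
        if rng.random() < 0.5:
            while core.endswith("A"):
                core = core[:-1]
                absorbed_right += 1
            suffix = "A" * (tail_len + absorbed_right)
            decorations.append(("polyA", tail_len + absorbed_right))
        else:
            while core.startswith("T"):
                core = core[1:]
                absorbed_left += 1
            prefix = "T" * (tail_len + absorbed_left)
            decorations.append(("polyT", tail_len + absorbed_left))
    if config.adapter_5p and rng.random() < config.adapter_5p_prob:
        prefix = config.adapter_5p + prefix
        decorations.append(("adapter_5p", len(config.adapter_5p)))
    if config.adapter_3p and rng.random() < config.adapter_3p_prob:
        suffix = suffix + config.adapter_3p
        decorations.append(("adapter_3p", len(config.adapter_3p)))

    seq = list(core)
    n_sub = _apply_substitutions(seq, config.substitution_rate, rng)
    if n_sub:
        decorations.append(("substitutions", n_sub))
    n_indel = _apply_homopolymer_indels(seq, config.homopolymer_indel_rate, rng)
    if n_indel:
        decorations.append(("homopolymer_indels", n_indel))

    return prefix + "".join(seq) + suffix, decorations, absorbed_left, absorbed_right


def _draw_fragment(
    seq_len: int, config: SimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    length = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
    length = max(config.read_length_min, min(config.read_length_max, length))
    length = min(length, seq_len)
    start = int(rng.integers(0, seq_len - length + 1))
    return start, start + length


def simulate_reads(
    transcripts: TranscriptSet, config: SimConfig
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Sample decorated reads from a transcript set.

    Reads-per-transcript are multinomial with probabilities proportional to
    abundance**normalization_exponent (renormalized); each read is a
    uniformly placed fragment whose length follows the configured truncated
    normal law.  Returns the reads and a truth table with one row per read.
    """
    config.validate()
    if config.n_reads > 0 and len(transcripts) == 0:
        raise ValueError("cannot simulate reads from an empty transcript set")
    rng = np.random.default_rng(config.seed + 1)
    reads: list[SimulatedRead] = []
    if config.n_reads > 0:
        p = transcripts.abundances() ** config.normalization_exponent
        p /= p.sum()
        counts = rng.multinomial(config.n_reads, p)
        idx = 0
        for t, count in zip(transcripts, counts):
            for _ in range(count):
                start, end = _draw_fragment(len(t.sequence), config, rng)
                core = t.sequence[start:end]
                seq, decorations, left, right = _decorate(core, config, rng)
                reads.append(
                    SimulatedRead(
                        read_id=f"read{idx:07d}",
                        sequence=seq,
                        source_id=t.transcript_id,
                        source_interval=(start + left, end - right),
                        decorations=decorations,
                    )
                )
                idx += 1
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    return reads, truth_table(reads)


def spike_contaminants(
    reads: list[SimulatedRead],
    library: TranscriptSet,
    fraction: float,
    seed: int,
    config: SimConfig | None = None,
) -> list[SimulatedRead]:
    """Append round(fraction * len(reads)) contaminant reads from a foreign library.

    Contaminant reads are decorated with the same artifact model as the
    target-library reads and flagged ``is_contaminant=True``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    config = config if config is not None else SimConfig()
    n_add = int(round(fraction * len(reads)))
    if n_add == 0:
        return list(reads)
    if len(library) == 0:
        raise ValueError("contaminant library is empty")
    rng = np.random.default_rng(seed)
    p = library.abundances()
    picks = rng.choice(len(library), size=n_add, p=p)
    out = list(reads)
    for i, k in enumerate(picks):
        t = library[int(k)]
        start, end = _draw_fragment(len(t.sequence), config, rng)
        seq, decorations, left, right = _decorate(t.sequence[start:end], config, rng)
        out.append(
            SimulatedRead(
                read_id=f"contam{i:06d}",
                sequence=seq,
                source_id=t.transcript_id,
                source_interval=(start + left, end - right),
                is_contaminant=True,
                decorations=decorations,
            )
        )
    return out


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    """One row per read: source, interval, contaminant flag, decorations."""
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "source_id": [r.source_id for r in reads],
            "start": [r.source_interval[0] for r in reads],
            "end": [r.source_interval[1] for r in reads],
            "is_contaminant": [r.is_contaminant for r in reads],
            "decorations": [
                ";".join(f"{k}={n}" for k, n in r.decorations) for r in reads
            ],
        }
    )


# ---------------------------------------------------------------------------
# I/O


def write_fasta(path, records: Iterable[tuple[str, str]] | TranscriptSet) -> None:
    if isinstance(records, TranscriptSet):
        records = [(r.transcript_id, r.sequence) for r in records]
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path, reads: Iterable[SimulatedRead], quality: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")


def write_truth_table(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
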