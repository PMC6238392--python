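"""Ribosome density, the translation ratio R_t and start-aligned metagenes.

Ribosome density RD = RPF[RPM] / mRNA[RPM] is a translation-efficiency proxy;
it is reported both raw and normalized to the per-condition median RD of
mitochondrially encoded genes, whose expression is insensitive to cytosolic
stress and therefore serves as an invariant baseline.

R_t measures initiation stalling: the share of a gene's ribosome-protected
fragments (RPFs) concentrated in the first 100 nt of the CDS. Genes with a
uniform RPF distribution score low (genuinely translated, R_t <= 0.5); genes
with RPFs piled at the start score high (stalled, R_t > 0.5). Two forms are
provided: FRACTION (window reads over total CDS reads; the default) and
LITERAL_RPKM (length-normalized numerator and denominator, under which a
perfectly uniform gene scores exactly 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .m6a_calling import Assay, Condition, CoverageProfile
from .transcriptome import TranscriptModel

__all__ = [
    "TranslationClass",
    "RtMode",
    "CountRecord",
    "TranslationRecord",
    "MetageneDensity",
    "compute_rpm",
    "compute_rpkm",
    "compute_rd",
    "normalize_rd",
    "compute_rt",
    "classify_translation",
    "metagene_density",
    "rd_shift",
]


class TranslationClass(str, Enum):
    TRANSLATED = "TRANSLATED"
    STALLED = "STALLED"
    UNDETECTED = "UNDETECTED"


class RtMode(str, Enum):
    FRACTION = "FRACTION"
    LITERAL_RPKM = "LITERAL_RPKM"


def compute_rpm(reads: float, library_size: float) -> float:
    """Reads per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if reads < 0:
        raise ValueError("negative read count")
    return reads * 1e6 / library_size


def compute_rpkm(reads: float, library_size: float, length_nt: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("effective length must be positive")
    return compute_rpm(reads, library_size) * 1e3 / length_nt


@dataclass(frozen=True)
class CountRecord:
    """Per-transcript read count with its RPM/RPKM normalizations."""

    transcript_id: str
    assay: Assay
    condition: Condition
    reads: float
    rpm: float
    rpkm: float

    @classmethod
    def from_reads(
        cls,
        transcript_id: str,
        assay: Assay,
        condition: Condition,
        reads: float,
        library_size: float,
        length_nt: float,
    ) -> "CountRecord":
        return cls(
            transcript_id=transcript_id,
            assay=assay,
            condition=condition,
            reads=reads,
            rpm=compute_rpm(reads, library_size),
            rpkm=compute_rpkm(reads, library_size, length_nt),
        )


@dataclass
class TranslationRecord:
    """Per-transcript RD, R_t and translated/stalled/undetected class.

    ``rd_raw``/``rd_norm``/``r_t`` are NaN when undefined (no mRNA signal or
    no RPF reads).
    """

    transcript_id: str
    condition: Condition
    rd_raw: float = float("nan")
    rd_norm: float = float("nan")
    r_t: float = float("nan")
    label: TranslationClass = TranslationClass.UNDETECTED

    @property
    def detected(self) -> bool:
        return not math.isnan(self.r_t)


def compute_rd(rpf_rpm: float, mrna_rpm: float) -> float:
    """Ribosome density RPF[RPM]/mRNA[RPM]; NaN when mRNA signal is zero."""
    if mrna_rpm == 0:
        return float("nan")
    return rpf_rpm / mrna_rpm


def normalize_rd(
    records: Sequence[TranslationRecord],
    mito_ids: Iterable[str],
) -> list[TranslationRecord]:
    """Fill rd_norm = rd_raw / median mitochondrial rd_raw (one condition).

    Mitochondrial gene expression is stress-invariant, so this baseline makes
    RD comparable across conditions despite library-size renormalization.
    """
    mito = set(mito_ids)
    baseline_values = [
        r.rd_raw
        for r in records
        if r.transcript_id in mito and not math.isnan(r.rd_raw)
    ]
    if not baseline_values:
        raise ValueError(
            "no mitochondrial gene with defined RD — baseline unavailable"
        )
    baseline = float(np.median(baseline_values))
    if baseline <= 0:
        raise ValueError("mitochondrial RD baseline is zero")
    for r in records:
        r.rd_norm = r.rd_raw / baseline
    return list(records)


def compute_rt(
    rpf_profile: CoverageProfile,
    transcript: TranscriptModel,
    mode: RtMode = RtMode.FRACTION,
    window: int = 100,
) -> float:
    """Translation ratio of one gene's RPF profile.

    The window starts at the first CDS nucleotide and is truncated to the CDS
    length. FRACTION: window reads / total CDS reads (library factors
    cancel). LITERAL_RPKM: (window reads per window kb) / (CDS reads per CDS
    kb). Returns NaN when the CDS has no reads.
    """
    if rpf_profile.length != transcript.length:
        raise ValueError(
            f"{transcript.transcript_id}: RPF profile length "
            f"{rpf_profile.length} != transcript length {transcript.length}"
        )
    cds = rpf_profile.counts[transcript.cds_start : transcript.cds_end]
    total = cds.sum()
    if total == 0:
        return float("nan")
    win = min(window, transcript.cds_len)
    win_reads = cds[:win].sum()
    if mode is RtMode.FRACTION:
        return float(win_reads / total)
    return float((win_reads / win) / (total / transcript.cds_len))


def classify_translation(
    records: Sequence[TranslationRecord],
    r_t_threshold: float = 0.5,
) -> list[TranslationRecord]:
    """TRANSLATED iff r_t <= threshold, STALLED iff r_t > threshold."""
    for r in records:
        if math.isnan(r.r_t):
            r.label = TranslationClass.UNDETECTED
        elif r.r_t <= r_t_threshold:
            r.label = TranslationClass.TRANSLATED
        else:
            r.label = TranslationClass.STALLED
    return list(records)


@dataclass
class MetageneDensity:
    """Equal-weight average of per-gene start-aligned read densities."""

    offsets: np.ndarray
    mean_density: np.ndarray
    cumulative: np.ndarray
    n_genes: int


def metagene_density(
    profiles: Mapping[str, CoverageProfile],
    transcripts: Mapping[str, TranscriptModel],
    window: tuple[int, int] = (-50, 500),
) -> MetageneDensity:
    """Start-codon-aligned metagene: normalize each gene to sum 1, average.

    ``window`` is [lo, hi) in nt relative to the first CDS base (offset 0).
    Offsets a transcript does not cover contribute zero density for that
    gene. Genes with no reads in the window are skipped.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty metagene window")
    width = hi - lo
    acc = np.zeros(width)
    n_genes = 0
    for tx_id, profile in profiles.items():
        transcript = transcripts[tx_id]
        dens = np.zeros(width)
        start = transcript.cds_start + lo
        src_lo = max(start, 0)
        src_hi = min(transcript.cds_start + hi, transcript.length)
        if src_hi > src_lo:
            dens[src_lo - start : src_hi - start] = profile.counts[src_lo:src_hi]
        total = dens.sum()
        if total == 0:
            continue
        acc += dens / total
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no gene with reads in the metagene window")
    mean = acc / n_genes
    return MetageneDensity(
        offsets=np.arange(lo, hi),
        mean_density=mean,
        cumulative=np.cumsum(mean),
        n_genes=n_genes,
    )


def rd_shift(
    records_control: Sequence[TranslationRecord],
    records_stress: Sequence[TranslationRecord],
) -> float:
    """Median log2(RD_control / RD_stress) over genes detected in both.

    Uses rd_norm (mitochondria-baselined), so the value reports the genuine
    global translational repression rather than a library-size artifact.
    """
    control = {r.transcript_id: r.rd_norm for r in records_control}
    stress = {r.transcript_id: r.rd_norm for r in records_stress}
    ratios = []
    for tx_id, rd_c in control.items():
        rd_s = stress.get(tx_id, float("nan"))
        if math.isnan(rd_c) or math.isnan(rd_s) or rd_c <= 0 or rd_s <= 0:
            continue
        ratios.append(math.log2(rd_c / rd_s))
    if not ratios:
        raise ValueError("no gene detected in both conditions")
    return float(np.median(ratios))
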