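"""m6A peak calling from IP/input coverage and methylated-DRACH statistics.

The calling scheme mirrors antibody-based m6A sequencing (MeRIP): methylated
fragments are enriched in the IP library, so methylation shows up as
IP-over-input coverage excess. Per transcript, both profiles are internally
normalized by their own mean coverage, the input is subtracted from the IP,
and maximal runs of positive excess become peaks. Every predicted DRACH motif
whose pentamer intersects a peak is considered methylated; peaks covering no
motif are discarded. The per-transcript m6A/A ratio is the fraction of
predicted DRACH motifs called methylated.

Transcripts whose raw IP coverage never reaches ``coverage_min`` (default 15)
are excluded from calling altogether.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .transcriptome import MotifSite, Region, SegmentBinning, TranscriptModel

__all__ = [
    "Assay",
    "Condition",
    "CoverageProfile",
    "AdjustedProfile",
    "PeakInterval",
    "MethylationCall",
    "MethylationSummary",
    "normalize_profile",
    "adjust_profile",
    "call_peaks",
    "assign_peaks_to_motifs",
    "methylation_summary",
    "stress_induced_sites",
    "metagene_methylation",
    "merge_coverage_replicates",
    "call_transcript",
]


class Assay(str, Enum):
    M6A_IP = "M6A_IP"
    RNA_INPUT = "RNA_INPUT"
    RPF = "RPF"
    PARCLIP = "PARCLIP"


class Condition(str, Enum):
    CONTROL = "CONTROL"
    STRESS_200 = "STRESS_200"
    STRESS_500 = "STRESS_500"


@dataclass
class CoverageProfile:
    """Per-nucleotide read counts for one (assay, condition, replicate)."""

    transcript_id: str
    assay: Assay
    condition: Condition
    replicate: int
    counts: np.ndarray
    library_size: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D per-nucleotide vector")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.transcript_id}: negative coverage counts")
        if self.library_size <= 0:
            raise ValueError(f"{self.transcript_id}: non-positive library size")

    @property
    def length(self) -> int:
        return self.counts.size


@dataclass
class AdjustedProfile:
    """Mean-normalized IP minus mean-normalized input; may be negative."""

    transcript_id: str
    values: np.ndarray
    excluded: bool
    reason: str = "NONE"  # LOW_COVERAGE or NONE


@dataclass(frozen=True)
class PeakInterval:
    transcript_id: str
    start: int
    end: int
    height: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak span must be non-empty (start < end)")


@dataclass(frozen=True)
class MethylationCall:
    """One DRACH site judged methylated in one condition."""

    site: MotifSite
    condition: Condition
    peak: PeakInterval


@dataclass
class MethylationSummary:
    transcript_id: str
    condition: Condition
    n_predicted: int
    n_methylated: int

    @property
    def defined(self) -> bool:
        return self.n_predicted > 0

    @property
    def ratio(self) -> float:
        """The m6A/A statistic; NaN when no DRACH motif is predicted."""
        if not self.defined:
            return float("nan")
        return self.n_methylated / self.n_predicted


def normalize_profile(counts: np.ndarray | CoverageProfile) -> np.ndarray:
    """Divide a coverage vector by its own mean; all-zero input stays zero."""
    if isinstance(counts, CoverageProfile):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean() if counts.size else 0.0
    if mean == 0.0:
        return np.zeros_like(counts)
    return counts / mean


def adjust_profile(
    ip: CoverageProfile,
    input_profile: CoverageProfile,
    coverage_min: float = 15.0,
) -> AdjustedProfile:
    """Mean-normalized IP minus mean-normalized input for one transcript.

    The exclusion rule is applied to the *raw* IP coverage maximum: a
    transcript never reaching ``coverage_min`` reads at any position is
    flagged LOW_COVERAGE and excluded from peak calling.
    """
    if ip.transcript_id != input_profile.transcript_id:
        raise ValueError(
            f"IP/input transcript mismatch: {ip.transcript_id} vs "
            f"{input_profile.transcript_id}"
        )
    if ip.length != input_profile.length:
        raise ValueError(
            f"{ip.transcript_id}: IP length {ip.length} != input length "
            f"{input_profile.length} (inconsistent annotation)"
        )
    excluded = bool(ip.counts.max(initial=0.0) < coverage_min)
    values = normalize_profile(ip.counts) - normalize_profile(input_profile.counts)
    return AdjustedProfile(
        transcript_id=ip.transcript_id,
        values=values,
        excluded=excluded,
        reason="LOW_COVERAGE" if excluded else "NONE",
    )


def call_peaks(
    adjusted: AdjustedProfile,
    tau: float = 0.5,
    min_width: int = 10,
) -> list[PeakInterval]:
    """Maximal runs of adjusted excess > tau, at least ``min_width`` nt wide.

    Excluded profiles yield no peaks. Negative adjusted values are retained
    in the profile but peaks require strictly positive excess above tau.
    """
    if adjusted.excluded:
        return []
    above = adjusted.values > tau
    if not above.any():
        return []
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    peaks = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_width:
            peaks.append(
                PeakInterval(
                    transcript_id=adjusted.transcript_id,
                    start=int(start),
                    end=int(end),
                    height=float(adjusted.values[start:end].max()),
                )
            )
    return peaks


def assign_peaks_to_motifs(
    peaks: Sequence[PeakInterval],
    motifs: Sequence[MotifSite],
    condition: Condition,
) -> list[MethylationCall]:
    """Methylation calls for every motif whose pentamer intersects a peak.

    Peaks covering no motif are dropped; a motif covered by several peaks is
    called once (first covering peak in coordinate order).
    """
    calls: dict[MotifSite, MethylationCall] = {}
    for peak in sorted(peaks, key=lambda p: (p.start, p.end)):
        for site in motifs:
            if site.transcript_id != peak.transcript_id:
                raise ValueError(
                    f"peak on {peak.transcript_id} paired with motif on "
                    f"{site.transcript_id}"
                )
            if site in calls:
                continue
            if site.start < peak.end and peak.start < site.end:
                calls[site] = MethylationCall(site=site, condition=condition, peak=peak)
    return sorted(calls.values(), key=lambda c: c.site.start)


def methylation_summary(
    calls: Sequence[MethylationCall],
    motifs: Sequence[MotifSite],
    transcript: TranscriptModel,
    condition: Condition,
) -> MethylationSummary:
    """Per-transcript m6A/A: called motifs over predicted DRACH motifs."""
    called = {c.site for c in calls if c.condition == condition}
    if not called <= set(motifs):
        raise ValueError(f"{transcript.transcript_id}: call for unpredicted motif")
    return MethylationSummary(
        transcript_id=transcript.transcript_id,
        condition=condition,
        n_predicted=len(motifs),
        n_methylated=len(called),
    )


def stress_induced_sites(
    control_calls: Iterable[MethylationCall],
    stress_calls: Iterable[MethylationCall],
) -> set[MotifSite]:
    """Motifs methylated under stress but not under control (gains only)."""
    control = {c.site for c in control_calls}
    return {c.site for c in stress_calls} - control


def metagene_methylation(
    transcripts: Mapping[str, TranscriptModel],
    motifs_by_tx: Mapping[str, Sequence[MotifSite]],
    calls: Sequence[MethylationCall],
    binning: SegmentBinning | None = None,
):
    """Pooled per-bin methylation ratio across transcripts, one condition.

    For each bin: (methylated motifs with a_pos in the bin) / (predicted
    motifs with a_pos in the bin), pooled over all transcripts. Bins with no
    predicted motif get ratio NaN (missing, not zero). Transcripts with a
    nonempty segment shorter than its bin count cannot be binned and are
    skipped.

    Returns a pandas DataFrame with columns
    segment, bin, n_predicted, n_methylated, ratio — one row per global bin.
    """
    import pandas as pd

    binning = binning or SegmentBinning()
    n_pred = np.zeros(binning.n_total, dtype=int)
    n_meth = np.zeros(binning.n_total, dtype=int)
    called = {c.site for c in calls}
    for tx_id, transcript in transcripts.items():
        if not binning.fits(transcript):
            continue
        for site in motifs_by_tx.get(tx_id, ()):
            b = binning.global_bin(transcript, site.a_pos)
            n_pred[b] += 1
            if site in called:
                n_meth[b] += 1
    rows = []
    for b in range(binning.n_total):
        region, local = binning.region_of_bin(b)
        ratio = n_meth[b] / n_pred[b] if n_pred[b] else float("nan")
        rows.append(
            {
                "segment": region.value,
                "bin": local,
                "n_predicted": int(n_pred[b]),
                "n_methylated": int(n_meth[b]),
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def merge_coverage_replicates(
    rep1: Mapping[str, CoverageProfile],
    rep2: Mapping[str, CoverageProfile],
    min_r2: float = 0.9,
) -> dict[str, CoverageProfile]:
    """Sum replicate coverage after a Pearson r^2 concordance gate.

    r^2 is computed on log1p per-transcript total counts over the shared
    transcript universe; a merge below ``min_r2`` is refused. Library sizes
    are summed; the merged replicate index is 0.
    """
    shared = sorted(set(rep1) & set(rep2))
    if not shared:
        raise ValueError("replicates share no transcripts")
    t1 = np.array([rep1[t].counts.sum() for t in shared])
    t2 = np.array([rep2[t].counts.sum() for t in shared])
    r, _ = _stats.pearsonr(np.log1p(t1), np.log1p(t2))
    if r * r < min_r2:
        raise ValueError(
            f"discordant replicates: r^2 = {r * r:.3f} < {min_r2} — merge refused"
        )
    merged = {}
    for t in shared:
        a, b = rep1[t], rep2[t]
        if a.length != b.length:
            raise ValueError(f"{t}: replicate length mismatch")
        merged[t] = CoverageProfile(
            transcript_id=t,
            assay=a.assay,
            condition=a.condition,
            replicate=0,
            counts=a.counts + b.counts,
            library_size=a.library_size + b.library_size,
        )
    return merged


def call_transcript(
    ip: CoverageProfile,
    input_profile: CoverageProfile,
    motifs: Sequence[MotifSite],
    condition: Condition,
    coverage_min: float = 15.0,
    tau: float = 0.5,
    min_width: int = 10,
) -> tuple[AdjustedProfile, list[PeakInterval], list[MethylationCall]]:
    """Convenience: adjust -> call peaks -> assign motifs for one transcript."""
    adjusted = adjust_profile(ip, input_profile, coverage_min=coverage_min)
    peaks = call_peaks(adjusted, tau=tau, min_width=min_width)
    calls = assign_peaks_to_motifs(peaks, motifs, condition)
    return adjusted, peaks, calls
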