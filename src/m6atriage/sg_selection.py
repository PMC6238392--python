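"""Stress-granule client selection from whole-SG PAR-CLIP enrichment.

SG-associated transcripts are censused by cross-linking whole stress granules
and sequencing the co-purified mRNA (transcript-level PAR-CLIP). A transcript
is selected as an SG client when its PAR-CLIP abundance under stress is
enriched over the unstressed control beyond a log2 cutoff (default log2 >= 1,
i.e. twofold; the cutoff is configurable — see docs/methods.md for the
rationale and the alternative fourfold reading). The SG metagene set is the
union of PAR-CLIP-selected clients and transcripts classified as stalled in
ribosome profiling, each member tagged with its provenance.

Detection floors are calibrated from spike-ins of known concentration:
the detection threshold of a library is the smallest RPKM among spike-ins
observed in every replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .m6a_calling import Assay, Condition
from .ribo_translation import CountRecord, compute_rpkm, compute_rpm

__all__ = [
    "CountTable",
    "DetectionThreshold",
    "EnrichmentRecord",
    "spikein_threshold",
    "detect_expressed",
    "merge_replicates",
    "parclip_enrichment",
    "merge_sg_set",
]


@dataclass
class CountTable:
    """Per-transcript read counts for one library, with normalizations.

    ``reads`` and ``effective_length`` are pandas Series indexed by
    transcript_id over the same universe.
    """

    assay: Assay
    condition: Condition
    replicate: int
    reads: pd.Series
    library_size: float
    effective_length: pd.Series

    def __post_init__(self) -> None:
        self.reads = self.reads.astype(float)
        if self.library_size <= 0:
            raise ValueError("non-positive library size")
        if not self.reads.index.equals(self.effective_length.index):
            self.effective_length = self.effective_length.reindex(self.reads.index)
            if self.effective_length.isna().any():
                missing = self.effective_length.index[self.effective_length.isna()]
                raise ValueError(f"no effective length for {list(missing[:3])} ...")
        if (self.effective_length <= 0).any():
            raise ValueError("non-positive effective length")
        if (self.reads < 0).any():
            raise ValueError("negative read counts")

    @property
    def rpm(self) -> pd.Series:
        return self.reads * 1e6 / self.library_size

    @property
    def rpkm(self) -> pd.Series:
        return self.rpm * 1e3 / self.effective_length

    def record(self, transcript_id: str) -> CountRecord:
        return CountRecord(
            transcript_id=transcript_id,
            assay=self.assay,
            condition=self.condition,
            reads=float(self.reads[transcript_id]),
            rpm=float(self.rpm[transcript_id]),
            rpkm=float(self.rpkm[transcript_id]),
        )


@dataclass(frozen=True)
class DetectionThreshold:
    """Spike-in-derived RPKM detection floor for one library/condition."""

    condition: Condition
    rpkm_min: float

    def __post_init__(self) -> None:
        if self.rpkm_min < 0:
            raise ValueError("negative detection threshold")


@dataclass
class EnrichmentRecord:
    """Per-transcript PAR-CLIP stress/control enrichment and SG-client flag."""

    transcript_id: str
    rpkm_control: float
    rpkm_stress: float
    log2_enrichment: float
    is_sg_client: bool


def spikein_threshold(
    replicates: Sequence[CountTable],
    spikein_ids: Iterable[str],
    condition: Condition | None = None,
) -> DetectionThreshold:
    """Detection floor: minimum mean RPKM among fully observed spike-ins.

    A spike-in qualifies only when it has nonzero counts in *every*
    replicate; the threshold is the minimum across qualifying spike-ins of
    the mean RPKM over replicates.
    """
    if not replicates:
        raise ValueError("no replicate count tables supplied")
    spikes = [s for s in spikein_ids if all(s in t.reads.index for t in replicates)]
    qualifying = [
        s for s in spikes if all(t.reads[s] > 0 for t in replicates)
    ]
    if not qualifying:
        raise ValueError(
            "no spike-in with nonzero counts in all replicates — "
            "library cannot be calibrated"
        )
    mean_rpkm = {
        s: float(np.mean([t.rpkm[s] for t in replicates])) for s in qualifying
    }
    return DetectionThreshold(
        condition=condition or replicates[0].condition,
        rpkm_min=min(mean_rpkm.values()),
    )


def detect_expressed(
    table: CountTable,
    threshold: DetectionThreshold,
    exclude: Iterable[str] = (),
) -> set[str]:
    """Transcripts at or above the detection floor (inclusive >=)."""
    excluded = set(exclude)
    rpkm = table.rpkm
    return {
        t for t in table.reads.index
        if t not in excluded and rpkm[t] >= threshold.rpkm_min
    }


def merge_replicates(
    rep1: CountTable,
    rep2: CountTable,
    min_r2: float = 0.9,
) -> CountTable:
    """Sum two biological replicates after a Pearson r^2 concordance gate.

    r^2 is computed on log RPKM of transcripts detected (reads > 0) in both
    replicates; a merge below ``min_r2`` is refused with an error. Counts and
    library sizes are summed; the merged replicate index is 0.
    """
    if not rep1.reads.index.equals(rep2.reads.index):
        raise ValueError("replicates cover different transcript universes")
    both = (rep1.reads > 0) & (rep2.reads > 0)
    if both.sum() < 2:
        raise ValueError("fewer than 2 co-detected transcripts")
    r, _ = _stats.pearsonr(
        np.log(rep1.rpkm[both]), np.log(rep2.rpkm[both])
    )
    if r * r < min_r2:
        raise ValueError(
            f"discordant replicates: r^2 = {r * r:.3f} < {min_r2} — merge refused"
        )
    return CountTable(
        assay=rep1.assay,
        condition=rep1.condition,
        replicate=0,
        reads=rep1.reads + rep2.reads,
        library_size=rep1.library_size + rep2.library_size,
        effective_length=rep1.effective_length,
    )


def parclip_enrichment(
    stress: CountTable,
    control: CountTable,
    log2_cutoff: float = 1.0,
    epsilon: float | None = None,
    detection: DetectionThreshold | None = None,
) -> list[EnrichmentRecord]:
    """log2((RPKM_stress + eps)/(RPKM_control + eps)) and SG-client flags.

    The pseudocount defaults to half the smallest nonzero RPKM across the two
    libraries, keeping the ratio defined for control-absent transcripts. A
    client must be detected in stress (above the spike-in floor when one is
    supplied, otherwise RPKM > 0) and enriched at or beyond the cutoff
    (inclusive >=).
    """
    if not stress.reads.index.equals(control.reads.index):
        raise ValueError("stress/control cover different transcript universes")
    rpkm_s, rpkm_c = stress.rpkm, control.rpkm
    if epsilon is None:
        nonzero = np.concatenate(
            [rpkm_s[rpkm_s > 0].to_numpy(), rpkm_c[rpkm_c > 0].to_numpy()]
        )
        if nonzero.size == 0:
            raise ValueError("both libraries are empty — pseudocount undefined")
        epsilon = float(nonzero.min()) / 2.0
    floor = detection.rpkm_min if detection is not None else 0.0
    records = []
    for tx in stress.reads.index:
        s, c = float(rpkm_s[tx]), float(rpkm_c[tx])
        # difference of logs, so swapping conditions negates the value exactly
        log2_enr = math.log2(s + epsilon) - math.log2(c + epsilon)
        detected = s >= floor if detection is not None else s > 0
        records.append(
            EnrichmentRecord(
                transcript_id=tx,
                rpkm_control=c,
                rpkm_stress=s,
                log2_enrichment=log2_enr,
                is_sg_client=bool(detected and log2_enr >= log2_cutoff),
            )
        )
    return records


def merge_sg_set(
    parclip_clients: Iterable[str],
    stalled_set: Iterable[str],
) -> dict[str, str]:
    """Union of PAR-CLIP clients and stalled transcripts with provenance.

    Returns transcript_id -> tag in {PARCLIP, STALLED, BOTH}.
    """
    parclip = set(parclip_clients)
    stalled = set(stalled_set)
    out = {}
    for tx in parclip | stalled:
        if tx in parclip and tx in stalled:
            out[tx] = "BOTH"
        elif tx in parclip:
            out[tx] = "PARCLIP"
        else:
            out[tx] = "STALLED"
    return out
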