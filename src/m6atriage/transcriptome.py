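"""Transcript data model, DRACH motif scanning and transcript-segment binning.

A transcript is represented in its own coordinate space (not genomic): the
sequence is the spliced mRNA, partitioned into 5'UTR, CDS and 3'UTR by the
annotated segment lengths. m6A is deposited on the central adenosine of the
degenerate DRACH pentamer (D = A/G/U, R = A/G, then A-C, H = U/A/C); all
scanning is done in the DNA alphabet with T standing in for U.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import itertools
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Region",
    "TranscriptModel",
    "MotifSite",
    "SegmentBinning",
    "DRACH_PATTERN",
    "enumerate_drach_pentamers",
    "scan_drach",
    "assign_region",
    "bin_segments",
    "select_longest_isoform",
]


class Region(str, Enum):
    """Transcript segment holding a position: 5'UTR, CDS or 3'UTR."""

    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


#: DRACH in the DNA alphabet. The lookahead makes overlapping matches visible.
DRACH_PATTERN = re.compile(r"(?=([AGT][AG]AC[TAC]))")

_VALID_BASES = frozenset("ACGT")


def enumerate_drach_pentamers() -> frozenset[str]:
    """All pentamers matching the DRACH consensus (DNA alphabet).

    D = A/G/T, R = A/G, positions 3-4 fixed A-C, H = T/A/C; 3*2*1*1*3 = 18
    pentamers in total.
    """
    return frozenset(
        "".join(p) for p in itertools.product("AGT", "AG", "A", "C", "TAC")
    )


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus segment geometry and gene-class flags.

    ``sequence`` is upper-cased and U is read as T on construction. The three
    segment lengths must tile the sequence exactly.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    is_mitochondrial: bool = False
    is_spikein: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.transcript_id}: negative UTR length")
        if self.cds_len < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than one codon")
        if self.utr5_len + self.cds_len + self.utr3_len != len(seq):
            raise ValueError(
                f"{self.transcript_id}: segment lengths "
                f"{self.utr5_len}+{self.cds_len}+{self.utr3_len} "
                f"do not sum to sequence length {len(seq)}"
            )
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters {sorted(bad)} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_start(self) -> int:
        """Offset of the first CDS base (the A of the start codon)."""
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    def segment_length(self, region: Region) -> int:
        return {
            Region.UTR5: self.utr5_len,
            Region.CDS: self.cds_len,
            Region.UTR3: self.utr3_len,
        }[region]

    def segment_start(self, region: Region) -> int:
        return {
            Region.UTR5: 0,
            Region.CDS: self.utr5_len,
            Region.UTR3: self.utr5_len + self.cds_len,
        }[region]


@dataclass(frozen=True, order=True)
class MotifSite:
    """One DRACH occurrence; ``a_pos`` is the methylatable adenosine (start+2).

    The segment is assigned by ``a_pos`` since the methyl mark sits on that
    adenosine; a pentamer spanning a segment junction belongs to the segment
    of its A.
    """

    transcript_id: str
    start: int
    a_pos: int
    region: Region

    @property
    def end(self) -> int:
        """Half-open end of the pentamer span."""
        return self.start + 5


def assign_region(transcript: TranscriptModel, position: int) -> Region:
    """Segment containing ``position`` (half-open segment boundaries)."""
    if not 0 <= position < transcript.length:
        raise ValueError(
            f"position {position} outside transcript "
            f"{transcript.transcript_id} of length {transcript.length}"
        )
    if position < transcript.utr5_len:
        return Region.UTR5
    if position < transcript.cds_end:
        return Region.CDS
    return Region.UTR3


def scan_drach(transcript: TranscriptModel) -> list[MotifSite]:
    """Every DRACH occurrence in the transcript, sorted by start.

    Overlapping matches are all reported. Sequences shorter than 5 nt yield
    an empty list.
    """
    sites = []
    for m in DRACH_PATTERN.finditer(transcript.sequence):
        start = m.start()
        a_pos = start + 2
        sites.append(
            MotifSite(
                transcript_id=transcript.transcript_id,
                start=start,
                a_pos=a_pos,
                region=assign_region(transcript, a_pos),
            )
        )
    return sites


def select_longest_isoform(
    isoforms: Mapping[str, Sequence[TranscriptModel]],
) -> dict[str, TranscriptModel]:
    """Per gene, the longest isoform; ties broken by smallest transcript_id."""
    chosen: dict[str, TranscriptModel] = {}
    for gene_id, txs in isoforms.items():
        if not txs:
            raise ValueError(f"gene {gene_id}: empty isoform list")
        chosen[gene_id] = min(txs, key=lambda t: (-t.length, t.transcript_id))
    return chosen


@dataclass(frozen=True)
class SegmentBinning:
    """Partition of each transcript segment into a fixed number of bins.

    Bin b of a segment of length L covers positions [floor(bL/n),
    floor((b+1)L/n)): contiguous spans whose sizes differ by at most 1 nt.
    Global bin indices run 0..n_total-1 in 5'->3' order (UTR5 bins first).
    """

    n_bins_utr5: int = 10
    n_bins_cds: int = 30
    n_bins_utr3: int = 10

    def __post_init__(self) -> None:
        if min(self.n_bins_utr5, self.n_bins_cds, self.n_bins_utr3) < 1:
            raise ValueError("bin counts must be positive")

    @property
    def n_total(self) -> int:
        return self.n_bins_utr5 + self.n_bins_cds + self.n_bins_utr3

    def n_bins(self, region: Region) -> int:
        return {
            Region.UTR5: self.n_bins_utr5,
            Region.CDS: self.n_bins_cds,
            Region.UTR3: self.n_bins_utr3,
        }[region]

    def bin_offset(self, region: Region) -> int:
        """Global index of the segment's first bin."""
        if region is Region.UTR5:
            return 0
        if region is Region.CDS:
            return self.n_bins_utr5
        return self.n_bins_utr5 + self.n_bins_cds

    def region_of_bin(self, global_bin: int) -> tuple[Region, int]:
        """Inverse of the global index: (segment, bin-within-segment)."""
        if not 0 <= global_bin < self.n_total:
            raise ValueError(f"bin {global_bin} out of range")
        if global_bin < self.n_bins_utr5:
            return Region.UTR5, global_bin
        if global_bin < self.n_bins_utr5 + self.n_bins_cds:
            return Region.CDS, global_bin - self.n_bins_utr5
        return Region.UTR3, global_bin - self.n_bins_utr5 - self.n_bins_cds

    @staticmethod
    def bin_edges(length: int, n_bins: int) -> list[int]:
        """Half-open bin boundaries [e0, e1, ..., en] with e_b = floor(bL/n)."""
        return [b * length // n_bins for b in range(n_bins + 1)]

    def fits(self, transcript: TranscriptModel) -> bool:
        """True when every nonempty segment is at least as long as its bins."""
        return all(
            transcript.segment_length(r) == 0
            or transcript.segment_length(r) >= self.n_bins(r)
            for r in Region
        )

    def position_to_bin(
        self, transcript: TranscriptModel, position: int
    ) -> tuple[Region, int]:
        """(segment, bin index within segment) for one position."""
        region = assign_region(transcript, position)
        length = transcript.segment_length(region)
        n = self.n_bins(region)
        if length < n:
            raise ValueError(
                f"{transcript.transcript_id}: segment {region.value} of "
                f"length {length} cannot hold {n} bins"
            )
        offset = position - transcript.segment_start(region)
        edges = self.bin_edges(length, n)
        return region, bisect_right(edges, offset) - 1

    def global_bin(self, transcript: TranscriptModel, position: int) -> int:
        region, b = self.position_to_bin(transcript, position)
        return self.bin_offset(region) + b


def bin_segments(
    transcript: TranscriptModel, binning: SegmentBinning
) -> np.ndarray:
    """Global bin index for every transcript position (length-L int array).

    Raises on over-binning (a nonempty segment shorter than its bin count);
    zero-length segments simply contribute no positions.
    """
    out = np.empty(transcript.length, dtype=np.int64)
    for region in Region:
        length = transcript.segment_length(region)
        if length == 0:
            continue
        n = binning.n_bins(region)
        if length < n:
            raise ValueError(
                f"{transcript.transcript_id}: segment {region.value} of "
                f"length {length} cannot hold {n} bins"
            )
        edges = np.asarray(SegmentBinning.bin_edges(length, n))
        local = np.searchsorted(edges, np.arange(length), side="right") - 1
        start = transcript.segment_start(region)
        out[start : start + length] = binning.bin_offset(region) + local
    return out
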