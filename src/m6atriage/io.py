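"""File formats and run configuration.

All stage inputs and outputs are plain text: FASTA for sequences, a
tab-delimited annotation table for transcript geometry, bedGraph for
per-nucleotide coverage, and headered TSV for counts and results.

The bedGraph "chrom" column carries *transcript IDs* — coverage lives in
transcript coordinate space, not genome space. Intervals are 0-based
half-open; positions absent from the file are zero. A leading
``# library_size=<N>`` comment records the library's total mapped reads
(without it, the sum of the file's counts is used). Parsing is strict:
malformed lines, unknown transcript IDs, out-of-range or overlapping
intervals abort with a line-numbered error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .transcriptome import SegmentBinning, TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "build_transcripts",
    "read_bedgraph",
    "write_bedgraph",
    "read_count_table",
    "write_count_table",
    "write_tsv",
    "read_yaml",
    "write_yaml",
    "RunConfig",
]

ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_id",
    "utr5_len",
    "cds_len",
    "utr3_len",
    "is_mitochondrial",
    "is_spikein",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by the first whitespace-delimited token of the ID line."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate transcript ID {record.id}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return sequences


def write_fasta(
    transcripts: Mapping[str, TranscriptModel] | Mapping[str, str],
    path: str | Path,
) -> None:
    records = []
    for tx_id in sorted(transcripts):
        entry = transcripts[tx_id]
        seq = entry.sequence if isinstance(entry, TranscriptModel) else entry
        records.append(SeqRecord(Seq(seq), id=tx_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV with the fixed column set; flags are 0/1."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValueError(f"{path}: duplicate transcript_id {dup}")
    for col in ("is_mitochondrial", "is_spikein"):
        if not df[col].isin((0, 1)).all():
            raise ValueError(f"{path}: column {col} must be 0/1")
    return df[ANNOTATION_COLUMNS]


def write_annotation(
    transcripts: Mapping[str, TranscriptModel], path: str | Path
) -> None:
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "utr5_len": m.utr5_len,
            "cds_len": m.cds_len,
            "utr3_len": m.utr3_len,
            "is_mitochondrial": int(m.is_mitochondrial),
            "is_spikein": int(m.is_spikein),
        }
        for _, m in sorted(transcripts.items())
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def build_transcripts(
    sequences: Mapping[str, str], annotation: pd.DataFrame
) -> dict[str, TranscriptModel]:
    """Join sequences with geometry; every sequence must be annotated."""
    ann = annotation.set_index("transcript_id")
    out: dict[str, TranscriptModel] = {}
    for tx_id, seq in sorted(sequences.items()):
        if tx_id not in ann.index:
            raise ValueError(f"transcript {tx_id} missing from annotation")
        row = ann.loc[tx_id]
        out[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=str(row["gene_id"]),
            sequence=seq,
            utr5_len=int(row["utr5_len"]),
            cds_len=int(row["cds_len"]),
            utr3_len=int(row["utr3_len"]),
            is_mitochondrial=bool(row["is_mitochondrial"]),
            is_spikein=bool(row["is_spikein"]),
        )
    return out


def write_bedgraph(profiles: Mapping[str, "CoverageProfile"], path: str | Path) -> None:
    """Run-length-encoded per-nucleotide coverage; zero runs are omitted."""
    lines = []
    library_size = None
    for tx_id in sorted(profiles):
        profile = profiles[tx_id]
        library_size = profile.library_size
        counts = profile.counts
        if counts.size == 0:
            continue
        change = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [counts.size]))
        for s, e in zip(starts, ends):
            v = counts[s]
            if v != 0:
                lines.append(f"{tx_id}\t{s}\t{e}\t{v:g}")
    with open(path, "w") as fh:
        if library_size is not None:
            fh.write(f"# library_size={library_size:g}\n")
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def read_bedgraph(
    path: str | Path, lengths: Mapping[str, int]
) -> tuple[dict[str, np.ndarray], float]:
    """Expand a transcript-space bedGraph to per-nucleotide vectors.

    Returns (vectors for *every* annotated transcript, library size).
    Strict: unknown IDs, malformed lines, out-of-range or overlapping
    intervals raise with the offending line number.
    """
    path = Path(path)
    vectors = {tx: np.zeros(length) for tx, length in lengths.items()}
    filled = {tx: np.zeros(length, dtype=bool) for tx, length in lengths.items()}
    library_size = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "library_size=" in line:
                    library_size = float(line.split("library_size=")[1])
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            tx_id, start_s, end_s, value_s = parts
            if tx_id not in vectors:
                raise ValueError(
                    f"{path}:{lineno}: transcript {tx_id} absent from annotation"
                )
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed fields") from exc
            if not 0 <= start < end <= lengths[tx_id]:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"{tx_id} of length {lengths[tx_id]}"
                )
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage")
            if filled[tx_id][start:end].any():
                raise ValueError(
                    f"{path}:{lineno}: overlapping intervals on {tx_id}"
                )
            filled[tx_id][start:end] = True
            vectors[tx_id][start:end] = value
    if library_size is None:
        library_size = float(sum(v.sum() for v in vectors.values()))
    return vectors, library_size


def write_count_table(table: "CountTable", path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "transcript_id": table.reads.index,
            "reads": table.reads.to_numpy(),
            "rpm": table.rpm.to_numpy(),
            "rpkm": table.rpkm.to_numpy(),
            "effective_length": table.effective_length.to_numpy(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# library_size={table.library_size:g}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_count_table(path, assay, condition, replicate) -> "CountTable":
    from .sg_selection import CountTable

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# library_size="):
            raise ValueError(f"{path}: missing library_size header")
        library_size = float(first.split("=")[1])
        df = pd.read_csv(fh, sep="\t")
    for col in ("transcript_id", "reads", "effective_length"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return CountTable(
        assay=assay,
        condition=condition,
        replicate=replicate,
        reads=pd.Series(df["reads"].to_numpy(), index=df["transcript_id"]),
        library_size=library_size,
        effective_length=pd.Series(
            df["effective_length"].to_numpy(), index=df["transcript_id"]
        ),
    )


def write_tsv(records, path: str | Path) -> None:
    """Headered, tab-delimited UTF-8 with stable column order."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)


@dataclass
class RunConfig:
    """All pipeline thresholds, resolved once and written into every output.

    Defaults carry the analysis constants: IP coverage exclusion below 15,
    peak threshold 0.5 normalized units over at least 10 nt, R_t cutoff 0.5
    (FRACTION mode), PAR-CLIP enrichment cutoff log2 >= 1 (twofold; the
    fourfold reading log2 >= 2 is available via this knob), replicate merge
    gate r^2 >= 0.9, and 10/30/10 segment binning.
    """

    coverage_min: float = 15.0
    tau: float = 0.5
    min_width: int = 10
    r_t_threshold: float = 0.5
    r_t_mode: str = "FRACTION"
    r_t_window: int = 100
    enrichment_log2_cutoff: float = 1.0
    min_r2: float = 0.9
    parclip_min_r2: float = 0.6
    n_bins_utr5: int = 10
    n_bins_cds: int = 30
    n_bins_utr3: int = 10
    cds_5prime_fraction: float = 0.2
    site_match_tolerance: int = 25
    seed: int = 42

    @property
    def binning(self) -> SegmentBinning:
        return SegmentBinning(self.n_bins_utr5, self.n_bins_cds, self.n_bins_utr3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = read_yaml(path)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        write_yaml(dataclasses.asdict(self), path)
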