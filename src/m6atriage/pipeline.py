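"""End-to-end orchestration: scan -> m6A calling -> ribo -> SG -> stats.

``run_pipeline`` consumes an in-memory dataset bundle (simulated or loaded
from a dataset directory) and a ``RunConfig`` and produces every stage
table plus a headline summary: peak counts, methylated-mRNA counts and
fractions, translated/stalled counts, the global RD shift, SG-client
counts, the fraction of SG clients methylated, and the attached statistics
(rank-sum comparison of m6A/A distributions, hypergeometric overlap of SG
clients with methylated transcripts).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .m6a_calling import (
    Assay,
    Condition,
    CoverageProfile,
    MethylationCall,
    MethylationSummary,
    PeakInterval,
    call_transcript,
    merge_coverage_replicates,
    metagene_methylation,
    methylation_summary,
    stress_induced_sites,
)
from .ribo_translation import (
    RtMode,
    TranslationClass,
    TranslationRecord,
    classify_translation,
    compute_rd,
    compute_rpm,
    compute_rt,
    normalize_rd,
    rd_shift,
)
from .sg_selection import (
    merge_replicates,
    merge_sg_set,
    parclip_enrichment,
)
from .stats_tests import hypergeometric_tail, mann_whitney_u, overlap_counts
from .synthetic_data import SyntheticDataset

__all__ = ["PipelineResult", "run_pipeline"]

M6A_CONDITIONS = (Condition.CONTROL, Condition.STRESS_500)
RIBO_CONDITIONS = (Condition.CONTROL, Condition.STRESS_200)


@dataclass
class PipelineResult:
    config: _io.RunConfig
    calls: dict[Condition, list[MethylationCall]]
    peaks: dict[Condition, list[PeakInterval]]
    summaries: dict[Condition, list[MethylationSummary]]
    metagene: dict[Condition, pd.DataFrame]
    translation: dict[Condition, list[TranslationRecord]]
    enrichment: list
    sg_set: dict[str, str]
    summary: dict

    def ratios(self, condition: Condition) -> np.ndarray:
        """Defined per-transcript m6A/A ratios for one condition."""
        return np.array(
            [s.ratio for s in self.summaries[condition] if s.defined]
        )


def _run_m6a(dataset: SyntheticDataset, config: _io.RunConfig):
    calls, peaks, summaries = {}, {}, {}
    for cond in M6A_CONDITIONS:
        ip = merge_coverage_replicates(
            dataset.coverage[(Assay.M6A_IP, cond, 1)],
            dataset.coverage[(Assay.M6A_IP, cond, 2)],
            min_r2=config.min_r2,
        )
        inp = merge_coverage_replicates(
            dataset.coverage[(Assay.RNA_INPUT, cond, 1)],
            dataset.coverage[(Assay.RNA_INPUT, cond, 2)],
            min_r2=config.min_r2,
        )
        cond_calls: list[MethylationCall] = []
        cond_peaks: list[PeakInterval] = []
        cond_summaries: list[MethylationSummary] = []
        for tx in sorted(dataset.transcripts):
            model = dataset.transcripts[tx]
            if model.is_spikein:
                continue
            motifs = dataset.motifs[tx]
            _, tx_peaks, tx_calls = call_transcript(
                ip[tx],
                inp[tx],
                motifs,
                cond,
                coverage_min=config.coverage_min,
                tau=config.tau,
                min_width=config.min_width,
            )
            cond_peaks.extend(p for p in tx_peaks
                              if any(s.start < p.end and p.start < s.end
                                     for s in motifs))
            cond_calls.extend(tx_calls)
            cond_summaries.append(methylation_summary(tx_calls, motifs, model, cond))
        calls[cond], peaks[cond], summaries[cond] = (
            cond_calls, cond_peaks, cond_summaries,
        )
    return calls, peaks, summaries


def _run_ribo(dataset: SyntheticDataset, config: _io.RunConfig):
    translation: dict[Condition, list[TranslationRecord]] = {}
    mito = dataset.mito_ids
    for cond in RIBO_CONDITIONS:
        rpf = dataset.coverage[(Assay.RPF, cond, 1)]
        mrna = dataset.counts[(Assay.RNA_INPUT, cond, 1)]
        rpf_library = next(iter(rpf.values())).library_size
        records = []
        for tx in sorted(rpf):
            model = dataset.transcripts[tx]
            rpf_reads = float(rpf[tx].counts.sum())
            rd_raw = compute_rd(
                compute_rpm(rpf_reads, rpf_library),
                float(mrna.rpm.get(tx, 0.0)),
            )
            r_t = compute_rt(
                rpf[tx],
                model,
                mode=RtMode(config.r_t_mode),
                window=config.r_t_window,
            )
            records.append(
                TranslationRecord(
                    transcript_id=tx, condition=cond, rd_raw=rd_raw, r_t=r_t
                )
            )
        normalize_rd(records, mito)
        classify_translation(records, r_t_threshold=config.r_t_threshold)
        translation[cond] = records
    return translation


def run_pipeline(
    dataset: SyntheticDataset,
    config: _io.RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage on a dataset bundle; optionally write all outputs."""
    config = config or _io.RunConfig()

    calls, peaks, summaries = _run_m6a(dataset, config)
    binning = config.binning
    metagene = {
        cond: metagene_methylation(
            {
                tx: m
                for tx, m in dataset.transcripts.items()
                if not m.is_spikein
            },
            dataset.motifs,
            calls[cond],
            binning,
        )
        for cond in M6A_CONDITIONS
    }
    induced = stress_induced_sites(
        calls[Condition.CONTROL], calls[Condition.STRESS_500]
    )

    translation = _run_ribo(dataset, config)
    shift = rd_shift(
        translation[Condition.CONTROL], translation[Condition.STRESS_200]
    )
    stalled = {
        r.transcript_id
        for r in translation[Condition.STRESS_200]
        if r.label is TranslationClass.STALLED
    }
    translated = {
        r.transcript_id
        for r in translation[Condition.STRESS_200]
        if r.label is TranslationClass.TRANSLATED
    }

    # PAR-CLIP replicates are noisier than the sequencing libraries (the
    # source data reported r^2 ~ 0.7 and still merged), hence the laxer gate.
    parclip_stress = merge_replicates(
        dataset.counts[(Assay.PARCLIP, Condition.STRESS_500, 1)],
        dataset.counts[(Assay.PARCLIP, Condition.STRESS_500, 2)],
        min_r2=config.parclip_min_r2,
    )
    parclip_control = merge_replicates(
        dataset.counts[(Assay.PARCLIP, Condition.CONTROL, 1)],
        dataset.counts[(Assay.PARCLIP, Condition.CONTROL, 2)],
        min_r2=config.parclip_min_r2,
    )
    enrichment = parclip_enrichment(
        parclip_stress,
        parclip_control,
        log2_cutoff=config.enrichment_log2_cutoff,
    )
    parclip_clients = {r.transcript_id for r in enrichment if r.is_sg_client}
    sg_set = merge_sg_set(parclip_clients, stalled)

    methylated = {
        cond: {s.transcript_id for s in summaries[cond] if s.n_methylated > 0}
        for cond in M6A_CONDITIONS
    }
    analyzed = {s.transcript_id for s in summaries[Condition.CONTROL] if s.defined}
    sg_methylated = set(sg_set) & methylated[Condition.STRESS_500]

    ratios_c = np.array([s.ratio for s in summaries[Condition.CONTROL] if s.defined])
    ratios_s = np.array(
        [s.ratio for s in summaries[Condition.STRESS_500] if s.defined]
    )
    mw = mann_whitney_u(ratios_c, ratios_s)
    universe = len(analyzed)
    hyper = hypergeometric_tail(
        k=len(sg_methylated & analyzed),
        K=len(set(sg_set) & analyzed),
        n=len(methylated[Condition.STRESS_500] & analyzed),
        N=universe,
    )
    venn = overlap_counts(
        {
            "methylated_control": methylated[Condition.CONTROL],
            "methylated_stress": methylated[Condition.STRESS_500],
        }
    )

    summary = {
        "n_transcripts_analyzed": universe,
        "n_peaks_control": len(peaks[Condition.CONTROL]),
        "n_peaks_stress": len(peaks[Condition.STRESS_500]),
        "n_methylated_mrnas_control": len(methylated[Condition.CONTROL]),
        "n_methylated_mrnas_stress": len(methylated[Condition.STRESS_500]),
        "pct_methylated_control": 100.0
        * len(methylated[Condition.CONTROL]) / max(universe, 1),
        "pct_methylated_stress": 100.0
        * len(methylated[Condition.STRESS_500]) / max(universe, 1),
        "n_stress_induced_sites": len(induced),
        "n_translated": len(translated),
        "n_stalled": len(stalled),
        "n_rpf_bearing": len(translated) + len(stalled),
        "rd_log2_shift": shift,
        "n_parclip_clients": len(parclip_clients),
        "n_sg_clients": len(sg_set),
        "pct_sg_clients_methylated": 100.0 * len(sg_methylated) / max(len(sg_set), 1),
        "m6a_ratio_mannwhitney_p": mw.p_value,
        "sg_methylated_hypergeom_p": hyper.p_value,
        "venn_methylated": {
            "control_only": venn.get(frozenset({"methylated_control"}), 0),
            "stress_only": venn.get(frozenset({"methylated_stress"}), 0),
            "both": venn.get(
                frozenset({"methylated_control", "methylated_stress"}), 0
            ),
        },
        "enrichment_cutoff_note": (
            "SG clients selected at log2 enrichment >= "
            f"{config.enrichment_log2_cutoff} (default twofold; the source "
            "protocol is also quotable as fourfold — see docs/methods.md)"
        ),
        "seed": config.seed,
    }

    result = PipelineResult(
        config=config,
        calls=calls,
        peaks=peaks,
        summaries=summaries,
        metagene=metagene,
        translation=translation,
        enrichment=enrichment,
        sg_set=sg_set,
        summary=summary,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    call_rows = [
        {
            "transcript_id": c.site.transcript_id,
            "motif_start": c.site.start,
            "a_pos": c.site.a_pos,
            "region": c.site.region.value,
            "condition": c.condition.value,
            "peak_start": c.peak.start,
            "peak_end": c.peak.end,
            "peak_height": c.peak.height,
        }
        for cond in result.calls
        for c in result.calls[cond]
    ]
    _io.write_tsv(
        pd.DataFrame(
            call_rows,
            columns=[
                "transcript_id", "motif_start", "a_pos", "region",
                "condition", "peak_start", "peak_end", "peak_height",
            ],
        ),
        outdir / "methylation_calls.tsv",
    )
    _io.write_tsv(
        pd.DataFrame(
            [
                {
                    "transcript_id": s.transcript_id,
                    "condition": s.condition.value,
                    "n_predicted": s.n_predicted,
                    "n_methylated": s.n_methylated,
                    "ratio": s.ratio,
                }
                for cond in result.summaries
                for s in result.summaries[cond]
            ]
        ),
        outdir / "methylation_summaries.tsv",
    )
    meta = pd.concat(
        [df.assign(condition=cond.value) for cond, df in result.metagene.items()],
        ignore_index=True,
    )
    _io.write_tsv(meta, outdir / "metagene_methylation.tsv")
    _io.write_tsv(
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "condition": r.condition.value,
                    "rd_raw": r.rd_raw,
                    "rd_norm": r.rd_norm,
                    "r_t": r.r_t,
                    "class": r.label.value,
                }
                for cond in result.translation
                for r in result.translation[cond]
            ]
        ),
        outdir / "translation.tsv",
    )
    _io.write_tsv(
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "rpkm_control": r.rpkm_control,
                    "rpkm_stress": r.rpkm_stress,
                    "log2_enrichment": r.log2_enrichment,
                    "is_sg_client": int(r.is_sg_client),
                    "provenance": result.sg_set.get(r.transcript_id, "NONE"),
                }
                for r in result.enrichment
            ]
        ),
        outdir / "sg_enrichment.tsv",
    )
    result.config.to_yaml(outdir / "run_config.yaml")
    config_hash = hashlib.sha256(
        (outdir / "run_config.yaml").read_bytes()
    ).hexdigest()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run.log", "w") as fh:
        import m6atriage

        fh.write(f"m6atriage version: {m6atriage.__version__}\n")
        fh.write(f"seed: {result.config.seed}\n")
        fh.write(f"config sha256: {config_hash}\n")
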