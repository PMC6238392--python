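"""Synthetic transcriptomes with planted methylation/translation/SG truth.

Every downstream stage of the pipeline is testable against planted ground
truth with no external download. The generator emulates the statistical
structure the analysis assumes:

* random-composition transcript sequences with annotated 5'UTR/CDS/3'UTR
  geometry, every nonempty segment guaranteed to contain at least one DRACH
  motif; mitochondrial and spike-in subsets flagged;
* a 3'UTR-biased baseline methylation state under control growth, with
  stress adding sites biased to the 5'UTR and 5' vicinity of the CDS on
  stress-granule client transcripts only;
* m6A-IP coverage as input expectation times a triangular enrichment kernel
  centred on each planted methylated adenosine (integer counts, Poisson
  noise, variance = mean);
* ribosome-profiling coverage that is uniform over the CDS for translated
  genes and concentrated in the first 100 CDS nt for stalled genes, with a
  global stress-induced ribosome-density reduction sparing mitochondrial
  genes;
* transcript-level PAR-CLIP counts with a fold enrichment for SG clients
  and multiplicative lognormal noise;
* ERCC-like spike-ins at known concentrations.

All randomness flows from a single seed through named `numpy` SeedSequence
children, so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .m6a_calling import Assay, Condition, CoverageProfile, MethylationCall
from .ribo_translation import TranslationClass, TranslationRecord
from .sg_selection import CountTable, EnrichmentRecord
from .transcriptome import (
    DRACH_PATTERN,
    MotifSite,
    Region,
    TranscriptModel,
    scan_drach,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_transcriptome",
    "plant_methylation",
    "simulate_coverage",
    "simulate_rpf",
    "simulate_rnaseq_counts",
    "simulate_parclip",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
    "score_site_recovery",
    "score_translation",
    "score_sg_selection",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Length and expression distributions are lognormal with hard minima so
    that every transcript can hold the default segment binning (10/30/10)
    and the 100-nt stall window. Magnitudes follow the analysed system:
    ~55% of transcripts are SG clients, stress adds 5'-biased methylation to
    70% of them, IP enrichment is 8-fold over a 50-nt triangular peak,
    stalled genes carry 85% of their footprints in the first 100 CDS nt, the
    global stress RD shift is log2 = 2.9, and PAR-CLIP clients are 4-fold
    enriched with 20% CV noise.
    """

    n_transcripts: int = 2000
    n_mitochondrial: int = 13
    n_spikeins: int = 20
    # (mu, sigma) of ln-length per segment, plus hard minima
    utr5_lognorm: tuple[float, float] = (math.log(150.0), 0.4)
    cds_lognorm: tuple[float, float] = (math.log(900.0), 0.4)
    utr3_lognorm: tuple[float, float] = (math.log(500.0), 0.5)
    min_utr5: int = 60
    min_cds: int = 300
    min_utr3: int = 60
    # per-nucleotide input coverage (expression proxy)
    coverage_mean: float = 60.0
    coverage_sigma: float = 0.5
    coverage_min: float = 30.0
    mito_expression_factor: float = 3.0
    # spike-in per-nucleotide coverage ladder (log-spaced)
    spikein_coverage_range: tuple[float, float] = (0.1, 20.0)
    # methylation ground truth
    fraction_sg_clients: float = 0.55
    control_methylation_rate: float = 0.4
    control_sites_poisson: float = 0.8
    control_region_weights: tuple[float, float, float] = (0.1, 0.2, 0.7)
    fraction_stress_methylated: float = 0.7
    stress_sites_poisson: float = 0.5
    cds_5prime_fraction: float = 0.2
    # m6A-IP signal
    ip_enrichment: float = 8.0
    peak_halfwidth: int = 25
    # ribosome profiling
    rpf_mean_reads: float = 500.0
    stall_fraction: float = 0.85
    stall_window: int = 100
    rd_log2_shift: float = 2.9
    # PAR-CLIP
    parclip_mean_reads: float = 200.0
    parclip_client_fold: float = 4.0
    parclip_noise_cv: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "fraction_sg_clients",
            "control_methylation_rate",
            "fraction_stress_methylated",
            "stall_fraction",
            "cds_5prime_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.n_mitochondrial + self.n_spikeins >= self.n_transcripts:
            raise ValueError("too few transcripts for the flagged subsets")
        if self.min_cds <= self.stall_window:
            raise ValueError("minimum CDS must exceed the stall window")


@dataclass
class GroundTruth:
    """Planted per-transcript truth sufficient to score every stage."""

    expression: dict[str, float]
    methylation: dict[Condition, dict[str, tuple[MotifSite, ...]]]
    translation: dict[Condition, dict[str, TranslationClass]]
    sg_clients: frozenset[str]


@dataclass
class SyntheticDataset:
    """In-memory bundle of transcriptome, truth and all libraries."""

    config: SimulationConfig
    transcripts: dict[str, TranscriptModel]
    motifs: dict[str, list[MotifSite]]
    truth: GroundTruth
    coverage: dict[tuple[Assay, Condition, int], dict[str, CoverageProfile]]
    counts: dict[tuple[Assay, Condition, int], CountTable]

    @property
    def mito_ids(self) -> set[str]:
        return {t for t, m in self.transcripts.items() if m.is_mitochondrial}

    @property
    def spikein_ids(self) -> set[str]:
        return {t for t, m in self.transcripts.items() if m.is_spikein}


def _draw_lengths(
    rng: np.random.Generator, n: int, lognorm: tuple[float, float], minimum: int
) -> np.ndarray:
    mu, sigma = lognorm
    lengths = np.maximum(rng.lognormal(mu, sigma, size=n).astype(int), minimum)
    return lengths


def _random_segment_with_drach(
    rng: np.random.Generator, length: int, max_tries: int = 200
) -> str:
    """Random A/C/G/T segment containing at least one full DRACH pentamer."""
    if length < 5:
        raise ValueError(f"segment of length {length} cannot contain a DRACH motif")
    for _ in range(max_tries):
        seq = "".join(rng.choice(_BASES, size=length))
        if DRACH_PATTERN.search(seq):
            return seq
    raise RuntimeError(f"no DRACH after {max_tries} draws for length {length}")


def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, TranscriptModel]:
    """Transcript models with guaranteed DRACH content per nonempty segment.

    Nuclear transcripts TX0001.. carry full 5'UTR/CDS/3'UTR geometry;
    mitochondrial transcripts (MT flag) and spike-ins (single-exon, CDS only)
    follow the same sequence model. One isoform per gene.
    """
    n_nuclear = config.n_transcripts - config.n_mitochondrial - config.n_spikeins
    transcripts: dict[str, TranscriptModel] = {}

    u5 = _draw_lengths(rng, config.n_transcripts, config.utr5_lognorm, config.min_utr5)
    cds = _draw_lengths(rng, config.n_transcripts, config.cds_lognorm, config.min_cds)
    cds -= cds % 3
    u3 = _draw_lengths(rng, config.n_transcripts, config.utr3_lognorm, config.min_utr3)

    idx = 0
    for i in range(n_nuclear):
        tx_id = f"TX{i + 1:05d}"
        seq = (
            _random_segment_with_drach(rng, int(u5[idx]))
            + _random_segment_with_drach(rng, int(cds[idx]))
            + _random_segment_with_drach(rng, int(u3[idx]))
        )
        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=f"G{i + 1:05d}",
            sequence=seq,
            utr5_len=int(u5[idx]),
            cds_len=int(cds[idx]),
            utr3_len=int(u3[idx]),
        )
        idx += 1
    for i in range(config.n_mitochondrial):
        tx_id = f"MT{i + 1:03d}"
        seq = (
            _random_segment_with_drach(rng, int(u5[idx]))
            + _random_segment_with_drach(rng, int(cds[idx]))
            + _random_segment_with_drach(rng, int(u3[idx]))
        )
        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=f"MTG{i + 1:03d}",
            sequence=seq,
            utr5_len=int(u5[idx]),
            cds_len=int(cds[idx]),
            utr3_len=int(u3[idx]),
            is_mitochondrial=True,
        )
        idx += 1
    for i in range(config.n_spikeins):
        tx_id = f"SPIKE{i + 1:03d}"
        length = int(cds[idx])
        seq = _random_segment_with_drach(rng, length)
        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=tx_id,
            sequence=seq,
            utr5_len=0,
            cds_len=length,
            utr3_len=0,
            is_spikein=True,
        )
        idx += 1
    return transcripts


def _plant_expression(
    config: SimulationConfig,
    transcripts: Mapping[str, TranscriptModel],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-nucleotide expected input coverage per transcript."""
    expr: dict[str, float] = {}
    spike_ids = sorted(t for t, m in transcripts.items() if m.is_spikein)
    lo, hi = config.spikein_coverage_range
    ladder = np.geomspace(lo, hi, num=max(len(spike_ids), 1))
    for i, tx in enumerate(spike_ids):
        expr[tx] = float(ladder[i])
    for tx, model in sorted(transcripts.items()):
        if model.is_spikein:
            continue
        level = max(
            rng.lognormal(math.log(config.coverage_mean), config.coverage_sigma),
            config.coverage_min,
        )
        if model.is_mitochondrial:
            level *= config.mito_expression_factor
        expr[tx] = float(level)
    return expr


def plant_methylation(
    transcripts: Mapping[str, TranscriptModel],
    motifs: Mapping[str, Sequence[MotifSite]],
    sg_clients: frozenset[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[Condition, dict[str, tuple[MotifSite, ...]]]:
    """Control (3'-biased) and stress (control plus 5'-biased gains) truth.

    Control sites are sampled over predicted DRACH motifs with per-region
    weights favouring the 3'UTR. Under stress, SG-client transcripts gain
    additional sites restricted to the 5'UTR and the first
    ``cds_5prime_fraction`` of the CDS. Mitochondrial and spike-in
    transcripts are never methylated.
    """
    w5, wc, w3 = config.control_region_weights
    control: dict[str, tuple[MotifSite, ...]] = {}
    stress: dict[str, tuple[MotifSite, ...]] = {}
    for tx in sorted(transcripts):
        model = transcripts[tx]
        sites = list(motifs.get(tx, ()))
        if model.is_spikein or model.is_mitochondrial or not sites:
            continue
        chosen: list[MotifSite] = []
        if rng.random() < config.control_methylation_rate:
            by_region = {r: [s for s in sites if s.region is r] for r in Region}
            weights = np.array(
                [
                    {Region.UTR5: w5, Region.CDS: wc, Region.UTR3: w3}[s.region]
                    / len(by_region[s.region])
                    for s in sites
                ]
            )
            n_eligible = int((weights > 0).sum())
            if n_eligible:
                weights /= weights.sum()
                k = min(1 + rng.poisson(config.control_sites_poisson), n_eligible)
                picked = rng.choice(len(sites), size=k, replace=False, p=weights)
                chosen = [sites[int(i)] for i in sorted(picked)]
        if chosen:
            control[tx] = tuple(chosen)

        gained: list[MotifSite] = []
        if tx in sg_clients and rng.random() < config.fraction_stress_methylated:
            five_prime_end = model.utr5_len + config.cds_5prime_fraction * model.cds_len
            pool = [
                s
                for s in sites
                if s.a_pos < five_prime_end and s not in chosen
            ]
            if pool:
                k = min(1 + rng.poisson(config.stress_sites_poisson), len(pool))
                picked = rng.choice(len(pool), size=k, replace=False)
                gained = [pool[int(i)] for i in sorted(picked)]
        merged = sorted(set(chosen) | set(gained))
        if merged:
            stress[tx] = tuple(merged)
    return {Condition.CONTROL: control, Condition.STRESS_500: stress}


def _triangular_kernel(
    length: int, sites: Sequence[MotifSite], halfwidth: int
) -> np.ndarray:
    """Pointwise max of unit triangles centred on each site's adenosine."""
    kernel = np.zeros(length)
    pos = np.arange(length)
    for site in sites:
        tri = np.maximum(0.0, 1.0 - np.abs(pos - site.a_pos) / halfwidth)
        np.maximum(kernel, tri, out=kernel)
    return kernel


def simulate_coverage(
    transcripts: Mapping[str, TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    assay: Assay,
    condition: Condition,
    replicate: int,
    rng: np.random.Generator,
) -> dict[str, CoverageProfile]:
    """One m6A-IP or RNA input coverage library (integer Poisson counts).

    Input expectation is flat at the transcript's expression level; IP
    expectation multiplies it by 1 + (enrichment - 1) * triangular kernel
    over the condition's planted sites.
    """
    if assay not in (Assay.M6A_IP, Assay.RNA_INPUT):
        raise ValueError(f"unsupported coverage assay {assay}")
    planted = truth.methylation.get(condition, {})
    raw: dict[str, np.ndarray] = {}
    for tx in sorted(transcripts):
        model = transcripts[tx]
        lam = np.full(model.length, truth.expression[tx])
        if assay is Assay.M6A_IP and tx in planted:
            kernel = _triangular_kernel(
                model.length, planted[tx], config.peak_halfwidth
            )
            lam = lam * (1.0 + (config.ip_enrichment - 1.0) * kernel)
        raw[tx] = rng.poisson(lam).astype(float)
    library_size = float(sum(c.sum() for c in raw.values()))
    return {
        tx: CoverageProfile(
            transcript_id=tx,
            assay=assay,
            condition=condition,
            replicate=replicate,
            counts=c,
            library_size=library_size,
        )
        for tx, c in raw.items()
    }


def simulate_rpf(
    transcripts: Mapping[str, TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    condition: Condition,
    rng: np.random.Generator,
    replicate: int = 1,
) -> dict[str, CoverageProfile]:
    """Ribosome-footprint coverage for one condition.

    Translated genes have uniform CDS expectation; stalled genes concentrate
    ``stall_fraction`` of their expected reads in the first ``stall_window``
    CDS nt. Under stress, nuclear-gene RPF expectation is scaled by
    2**(-rd_log2_shift); mitochondrial genes are unscaled. Spike-ins carry
    no footprints.
    """
    classes = truth.translation[condition]
    scale = 2.0 ** (-config.rd_log2_shift)
    raw: dict[str, np.ndarray] = {}
    for tx in sorted(classes):
        model = transcripts[tx]
        expr_rel = truth.expression[tx] / config.coverage_mean
        mean_reads = config.rpf_mean_reads * expr_rel
        if condition is not Condition.CONTROL and not model.is_mitochondrial:
            mean_reads *= scale
        lam = np.zeros(model.length)
        cds = slice(model.cds_start, model.cds_end)
        if classes[tx] is TranslationClass.STALLED:
            win = min(config.stall_window, model.cds_len)
            lam[model.cds_start : model.cds_start + win] = (
                config.stall_fraction * mean_reads / win
            )
            rest = model.cds_len - win
            if rest > 0:
                lam[model.cds_start + win : model.cds_end] = (
                    (1.0 - config.stall_fraction) * mean_reads / rest
                )
        else:
            lam[cds] = mean_reads / model.cds_len
        raw[tx] = rng.poisson(lam).astype(float)
    library_size = float(sum(c.sum() for c in raw.values()))
    return {
        tx: CoverageProfile(
            transcript_id=tx,
            assay=Assay.RPF,
            condition=condition,
            replicate=replicate,
            counts=c,
            library_size=library_size,
        )
        for tx, c in raw.items()
    }


def simulate_rnaseq_counts(
    transcripts: Mapping[str, TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    condition: Condition,
    rng: np.random.Generator,
    replicate: int = 1,
) -> CountTable:
    """Transcript-level RNA-Seq counts (expression is stress-invariant)."""
    ids = sorted(transcripts)
    expected = np.array(
        [truth.expression[t] * transcripts[t].length / 100.0 for t in ids]
    )
    reads = rng.poisson(expected).astype(float)
    lengths = pd.Series({t: float(transcripts[t].length) for t in ids})
    return CountTable(
        assay=Assay.RNA_INPUT,
        condition=condition,
        replicate=replicate,
        reads=pd.Series(reads, index=ids),
        library_size=float(reads.sum()),
        effective_length=lengths,
    )


def simulate_parclip(
    transcripts: Mapping[str, TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    condition: Condition,
    rng: np.random.Generator,
    n_replicates: int = 2,
) -> list[CountTable]:
    """Transcript-level PAR-CLIP counts, two replicates per condition.

    Stress counts of SG clients are the control expectation times
    ``parclip_client_fold``; non-clients stay at fold 1. Multiplicative
    lognormal noise with the configured CV (mean 1) is applied per
    transcript and replicate.

    Library sizes are depth-matched across conditions (the fixed nominal
    control depth), emulating spike-in-calibrated sequencing: cross-condition
    RPKM ratios then report genuine abundance folds rather than being
    compressed by the stress libraries' larger total signal.
    """
    ids = sorted(t for t in transcripts if not transcripts[t].is_spikein)
    sigma = math.sqrt(math.log(1.0 + config.parclip_noise_cv**2))
    base = np.array(
        [
            config.parclip_mean_reads * truth.expression[t] / config.coverage_mean
            for t in ids
        ]
    )
    nominal_depth = float(base.sum())
    if condition is not Condition.CONTROL:
        fold = np.array(
            [
                config.parclip_client_fold if t in truth.sg_clients else 1.0
                for t in ids
            ]
        )
        base = base * fold
    lengths = pd.Series({t: float(transcripts[t].length) for t in ids})
    tables = []
    for rep in range(1, n_replicates + 1):
        noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(ids))
        reads = np.round(base * noise)
        tables.append(
            CountTable(
                assay=Assay.PARCLIP,
                condition=condition,
                replicate=rep,
                reads=pd.Series(reads, index=ids),
                library_size=nominal_depth,
                effective_length=lengths,
            )
        )
    return tables


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full dataset: transcriptome, truth and every library."""
    config = config or SimulationConfig()
    root = np.random.SeedSequence(config.seed)
    names = [
        "transcriptome",
        "expression",
        "sg_clients",
        "methylation",
        "ip_control_1",
        "ip_control_2",
        "ip_stress_1",
        "ip_stress_2",
        "input_control_1",
        "input_control_2",
        "input_stress_1",
        "input_stress_2",
        "rpf_control",
        "rpf_stress",
        "rnaseq_control",
        "rnaseq_stress",
        "parclip_control",
        "parclip_stress",
    ]
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }

    transcripts = generate_transcriptome(config, rngs["transcriptome"])
    motifs = {tx: scan_drach(m) for tx, m in sorted(transcripts.items())}
    expression = _plant_expression(config, transcripts, rngs["expression"])

    nuclear = sorted(
        t
        for t, m in transcripts.items()
        if not (m.is_mitochondrial or m.is_spikein)
    )
    n_clients = int(round(config.fraction_sg_clients * len(nuclear)))
    clients = frozenset(
        rngs["sg_clients"].choice(nuclear, size=n_clients, replace=False).tolist()
    )

    methylation = plant_methylation(
        transcripts, motifs, clients, config, rngs["methylation"]
    )
    translation = {
        Condition.CONTROL: {t: TranslationClass.TRANSLATED for t in nuclear},
        Condition.STRESS_200: {
            t: TranslationClass.STALLED
            if t in clients
            else TranslationClass.TRANSLATED
            for t in nuclear
        },
    }
    for cond in (Condition.CONTROL, Condition.STRESS_200):
        for t in sorted(transcripts):
            if transcripts[t].is_mitochondrial:
                translation[cond][t] = TranslationClass.TRANSLATED

    truth = GroundTruth(
        expression=expression,
        methylation=methylation,
        translation=translation,
        sg_clients=clients,
    )

    coverage: dict[tuple[Assay, Condition, int], dict[str, CoverageProfile]] = {}
    for cond, tag in ((Condition.CONTROL, "control"), (Condition.STRESS_500, "stress")):
        for rep in (1, 2):
            coverage[(Assay.M6A_IP, cond, rep)] = simulate_coverage(
                transcripts, truth, config, Assay.M6A_IP, cond, rep,
                rngs[f"ip_{tag}_{rep}"],
            )
            coverage[(Assay.RNA_INPUT, cond, rep)] = simulate_coverage(
                transcripts, truth, config, Assay.RNA_INPUT, cond, rep,
                rngs[f"input_{tag}_{rep}"],
            )
    coverage[(Assay.RPF, Condition.CONTROL, 1)] = simulate_rpf(
        transcripts, truth, config, Condition.CONTROL, rngs["rpf_control"]
    )
    coverage[(Assay.RPF, Condition.STRESS_200, 1)] = simulate_rpf(
        transcripts, truth, config, Condition.STRESS_200, rngs["rpf_stress"]
    )

    counts: dict[tuple[Assay, Condition, int], CountTable] = {
        (Assay.RNA_INPUT, Condition.CONTROL, 1): simulate_rnaseq_counts(
            transcripts, truth, config, Condition.CONTROL, rngs["rnaseq_control"]
        ),
        (Assay.RNA_INPUT, Condition.STRESS_200, 1): simulate_rnaseq_counts(
            transcripts, truth, config, Condition.STRESS_200, rngs["rnaseq_stress"]
        ),
    }
    for cond, tag in ((Condition.CONTROL, "control"), (Condition.STRESS_500, "stress")):
        for table in simulate_parclip(
            transcripts, truth, config, cond, rngs[f"parclip_{tag}"]
        ):
            counts[(Assay.PARCLIP, cond, table.replicate)] = table

    return SyntheticDataset(
        config=config,
        transcripts=transcripts,
        motifs=motifs,
        truth=truth,
        coverage=coverage,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# scoring against planted truth


def score_site_recovery(
    truth: GroundTruth,
    calls: Sequence[MethylationCall],
    condition: Condition,
    tolerance: int = 25,
) -> tuple[float, float]:
    """(sensitivity, precision) of methylation calls vs planted sites.

    A call is a true positive when its adenosine lies within ``tolerance``
    nt (one peak half-width) of a planted site on the same transcript; a
    planted site is recovered when some call lies within the tolerance. The
    calling rule deliberately marks every DRACH under a peak, so recovery is
    scored at peak resolution rather than base-exact motif identity.
    """
    planted = truth.methylation.get(condition, {})
    planted_pos = {tx: [s.a_pos for s in sites] for tx, sites in planted.items()}
    call_pos: dict[str, list[int]] = {}
    for c in calls:
        call_pos.setdefault(c.site.transcript_id, []).append(c.site.a_pos)

    n_planted = sum(len(v) for v in planted_pos.values())
    n_calls = sum(len(v) for v in call_pos.values())
    recovered = sum(
        1
        for tx, sites in planted_pos.items()
        for p in sites
        if any(abs(p - q) <= tolerance for q in call_pos.get(tx, ()))
    )
    true_calls = sum(
        1
        for tx, positions in call_pos.items()
        for q in positions
        if any(abs(p - q) <= tolerance for p in planted_pos.get(tx, ()))
    )
    sensitivity = recovered / n_planted if n_planted else float("nan")
    precision = true_calls / n_calls if n_calls else float("nan")
    return sensitivity, precision


def score_translation(
    truth: GroundTruth,
    records: Sequence[TranslationRecord],
    rpf_profiles: Mapping[str, CoverageProfile],
    condition: Condition,
    min_reads: float = 100.0,
) -> float:
    """Fraction of well-covered transcripts whose class matches the truth."""
    classes = truth.translation[condition]
    hits = total = 0
    for r in records:
        planted = classes.get(r.transcript_id)
        profile = rpf_profiles.get(r.transcript_id)
        if planted is None or profile is None or profile.counts.sum() < min_reads:
            continue
        total += 1
        hits += r.label is planted
    if total == 0:
        raise ValueError("no transcript passes the read-depth filter")
    return hits / total


def score_sg_selection(
    truth: GroundTruth,
    records: Sequence[EnrichmentRecord],
) -> dict[str, float]:
    """Precision/recall/F1 of SG-client flags against planted membership."""
    tp = fp = fn = 0
    for r in records:
        is_client = r.transcript_id in truth.sg_clients
        if r.is_sg_client and is_client:
            tp += 1
        elif r.is_sg_client:
            fp += 1
        elif is_client:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# on-disk form (all plain text; see io module for format primitives)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write FASTA, annotation, bedGraphs, count and truth TSVs, config."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(dataset.transcripts, outdir / "transcripts.fasta")
    _io.write_annotation(dataset.transcripts, outdir / "annotation.tsv")
    for (assay, cond, rep), profiles in sorted(dataset.coverage.items()):
        name = f"{assay.value}.{cond.value}.rep{rep}.bedgraph".lower()
        _io.write_bedgraph(profiles, outdir / name)
    for (assay, cond, rep), table in sorted(dataset.counts.items()):
        name = f"counts.{assay.value}.{cond.value}.rep{rep}.tsv".lower()
        _io.write_count_table(table, outdir / name)

    meth_rows = [
        {
            "condition": cond.value,
            "transcript_id": tx,
            "start": s.start,
            "a_pos": s.a_pos,
            "region": s.region.value,
        }
        for cond, per_tx in sorted(dataset.truth.methylation.items())
        for tx, sites in sorted(per_tx.items())
        for s in sites
    ]
    pd.DataFrame(
        meth_rows, columns=["condition", "transcript_id", "start", "a_pos", "region"]
    ).to_csv(outdir / "truth_methylation.tsv", sep="\t", index=False)

    trans_rows = [
        {"condition": cond.value, "transcript_id": tx, "class": label.value}
        for cond, per_tx in sorted(dataset.truth.translation.items())
        for tx, label in sorted(per_tx.items())
    ]
    pd.DataFrame(trans_rows).to_csv(
        outdir / "truth_translation.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"transcript_id": sorted(dataset.truth.sg_clients)}
    ).to_csv(outdir / "truth_sg_clients.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"transcript_id": tx, "expression": v}
            for tx, v in sorted(dataset.truth.expression.items())
        ]
    ).to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
    _io.write_yaml(asdict(dataset.config), outdir / "config.yaml")
    return outdir


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Reconstruct a written dataset directory into the in-memory bundle."""
    from . import io as _io

    indir = Path(indir)
    raw_cfg = _io.read_yaml(indir / "config.yaml")
    for key in ("utr5_lognorm", "cds_lognorm", "utr3_lognorm",
                "spikein_coverage_range", "control_region_weights"):
        raw_cfg[key] = tuple(raw_cfg[key])
    config = SimulationConfig(**raw_cfg)
    sequences = _io.read_fasta(indir / "transcripts.fasta")
    annotation = _io.read_annotation(indir / "annotation.tsv")
    transcripts = _io.build_transcripts(sequences, annotation)
    motifs = {tx: scan_drach(m) for tx, m in sorted(transcripts.items())}
    lengths = {tx: m.length for tx, m in transcripts.items()}

    coverage: dict[tuple[Assay, Condition, int], dict[str, CoverageProfile]] = {}
    for path in sorted(indir.glob("*.bedgraph")):
        assay_s, cond_s, rep_s = path.name.removesuffix(".bedgraph").split(".")
        assay = Assay(assay_s.upper())
        cond = Condition(cond_s.upper())
        rep = int(rep_s.removeprefix("rep"))
        vectors, library_size = _io.read_bedgraph(path, lengths)
        coverage[(assay, cond, rep)] = {
            tx: CoverageProfile(
                transcript_id=tx,
                assay=assay,
                condition=cond,
                replicate=rep,
                counts=vec,
                library_size=library_size,
            )
            for tx, vec in vectors.items()
        }
    counts: dict[tuple[Assay, Condition, int], CountTable] = {}
    for path in sorted(indir.glob("counts.*.tsv")):
        _, assay_s, cond_s, rep_s = path.name.removesuffix(".tsv").split(".")
        key = (
            Assay(assay_s.upper()),
            Condition(cond_s.upper()),
            int(rep_s.removeprefix("rep")),
        )
        counts[key] = _io.read_count_table(
            path, assay=key[0], condition=key[1], replicate=key[2]
        )

    meth = pd.read_csv(indir / "truth_methylation.tsv", sep="\t")
    methylation: dict[Condition, dict[str, tuple[MotifSite, ...]]] = {}
    for cond_s, group in meth.groupby("condition"):
        per_tx: dict[str, tuple[MotifSite, ...]] = {}
        for tx, rows in group.groupby("transcript_id"):
            per_tx[tx] = tuple(
                MotifSite(
                    transcript_id=tx,
                    start=int(r.start),
                    a_pos=int(r.a_pos),
                    region=Region(r.region),
                )
                for r in rows.itertuples()
            )
        methylation[Condition(cond_s)] = per_tx
    for cond in (Condition.CONTROL, Condition.STRESS_500):
        methylation.setdefault(cond, {})

    trans = pd.read_csv(indir / "truth_translation.tsv", sep="\t")
    translation = {
        Condition(cond_s): {
            tx: TranslationClass(label)
            for tx, label in zip(group["transcript_id"], group["class"])
        }
        for cond_s, group in trans.groupby("condition")
    }
    clients = frozenset(
        pd.read_csv(indir / "truth_sg_clients.tsv", sep="\t")["transcript_id"]
    )
    expr_df = pd.read_csv(indir / "truth_expression.tsv", sep="\t")
    expression = dict(zip(expr_df["transcript_id"], expr_df["expression"]))

    return SyntheticDataset(
        config=config,
        transcripts=transcripts,
        motifs=motifs,
        truth=GroundTruth(
            expression=expression,
            methylation=methylation,
            translation=translation,
            sg_clients=clients,
        ),
        coverage=coverage,
        counts=counts,
    )
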