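# m6atriage

Transcript-level analysis of stress-induced m6A methylation and mRNA
triaging to stress granules.

Under oxidative stress, cells repress bulk translation and sequester
stalled mRNAs in stress granules (SGs). A selective layer sits on top of
this: stress induces N6-methyladenosine (m6A) marks in the 5'UTR and the
5' vicinity of the coding sequence, and those methylated transcripts are
preferentially routed to SGs. `m6atriage` implements the computational side
of that analysis for people working with transcript-coordinate sequencing
data (m6A-Seq/MeRIP, Ribo-Seq, transcript-level PAR-CLIP):

* **DRACH scanning and metagene binning** — exhaustive matching of the
  degenerate consensus (D = A/G/U, R = A/G, A, C, H = U/A/C; the methyl
  mark sits on the central A), with 5'UTR/CDS/3'UTR segment binning for
  length-comparable metagene profiles.
* **m6A calling** — per-gene mean normalization of IP and input coverage,
  input subtraction, threshold-and-run peak calling, and motif-level
  methylation calls; summarized as the per-transcript ratio m6A/A
  (methylated over predicted DRACH motifs).
* **Translation classification** — ribosome density RD = RPF[RPM]/mRNA[RPM]
  baselined to mitochondrial genes, and the translation ratio
  R_t = (RPF reads in the first 100 CDS nt)/(RPF reads over the CDS):
  R_t ≤ 0.5 marks genuinely translated genes, R_t > 0.5 marks initiation
  stalling.
* **SG-client selection** — spike-in detection floors, replicate merging
  behind a correlation gate, log2 PAR-CLIP stress/control enrichment, and
  the merged SG set (PAR-CLIP clients ∪ stalled transcripts).
* **Statistics** — Mann-Whitney rank-sum, upper-tail hypergeometric overlap
  tests, Pearson correlation, Venn counts.
* **Synthetic data** — a generator that plants methylation, translation and
  SG ground truth with realistic noise, so the whole pipeline is testable
  end to end with no download.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate a small study and run the full pipeline:

```sh
m6atriage simulate --seed 7 --n-transcripts 300 --out sim/
m6atriage run --dataset sim/ --seed 7 --out run/
```

or equivalently in Python:

```python
from m6atriage import SimulationConfig, generate_dataset, run_pipeline

dataset = generate_dataset(SimulationConfig(n_transcripts=300, seed=7))
result = run_pipeline(dataset, outdir="run/")
print(result.summary)
```

Selected output (from `run/summary.json`):

```json
{
  "n_transcripts_analyzed": 280,
  "n_peaks_control": 167,
  "n_peaks_stress": 319,
  "n_methylated_mrnas_control": 96,
  "n_methylated_mrnas_stress": 175,
  "n_translated": 133,
  "n_stalled": 147,
  "rd_log2_shift": 2.8366410880606576,
  "n_sg_clients": 147,
  "pct_sg_clients_methylated": 87.07482993197279,
  "m6a_ratio_mannwhitney_p": 1.537899990223598e-10,
  "sg_methylated_hypergeom_p": 6.879788501717569e-20
}
```

Reading it: of 280 analyzable transcripts (spike-ins excluded), 96 carry at
least one methylated DRACH under control growth and 175 under stress — the
m6A-peak count nearly doubles (167 → 319), and the per-transcript m6A/A
distributions differ by rank-sum p ≈ 1.5 × 10⁻¹⁰. Ribosome profiling under
mild stress classifies 133 genes as translated and 147 as stalled, with a
median ribosome-density drop of log2 ≈ 2.84 against the mitochondrial
baseline (the generator planted 2.9). The SG set contains 147 transcripts,
87% of them methylated, and the overlap between SG membership and
methylation is far beyond chance (hypergeometric p ≈ 7 × 10⁻²⁰).

Stage tables (`methylation_calls.tsv`, `metagene_methylation.tsv`,
`translation.tsv`, `sg_enrichment.tsv`), the resolved configuration and a
log are written next to `summary.json`; re-running with the same seed and
config reproduces them exactly.

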