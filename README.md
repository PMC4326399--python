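# her2snp

SNP-array analysis of *HER2* gene status in breast tumors, packaged as a
tested, reusable pipeline:

- **probe_io** — probe-level data model (chrom / pos / intensity / allele
  ratio), baseline-2 normalization (genome-wide mean intensity defined as 2),
  TSV and SEG readers/writers, and the packaged 65-sample clinical tables
  (IHC score, FISH HER2/CEP17 ratio, HER2 segment copy number, relation
  label, status; plus the per-sample polyploidy summary).
- **sim_genome** — synthetic tumor genomes with arbitrary karyotypes
  (focal amplifications/deletions, whole-genome polyploidy, copy-neutral
  LOH), normal-cell contamination, and Gaussian probe noise; plus named
  cohort scenarios (`diploid`, `her2_amp`, `coamp`, `polyploid`,
  `polyploid_her2_amp`, `cnloh`).
- **segmentation** — breakpoint detection by recursive bisection with a
  Welch t-test (p < 0.001), best-significance split selection, per-platform
  minimum probes per segment (SNP500K = 100, SNP6 = 200), and a minimum
  change magnitude of 0.3 × a robust per-chromosome noise estimate.
- **cn_calls** — copy-number status thresholds (< 1.8 deletion,
  [1.8, 2.2] normal, > 2.2 amplification), the HER2-locus call
  (chr17:37,642,255–37,970,066, Hg19) versus a configurable
  centromere-proximal window, fold strata (≥ 4-fold vs moderate), and
  cohort summaries.
- **ploidy** — allelic-band clustering (mirror-folded KDE), purity-aware
  copy quantization, and minimal-baseline ploidy search combining segment
  intensities with allelic balance; polyploid when the median implied copy
  number across chromosomes is ≥ 3.
- **clinical** — IHC/FISH classification (3+ positive; 2+ resolved by FISH
  at an inclusive cut-off of 2; 0/1+ negative), the virtual FISH ratio and
  its masking property, and the SNP-vs-IHC/FISH concordance analysis.
- **cli** — `her2snp` command with `simulate`, `segment`, `call`, `ploidy`,
  `concordance`, and `run` subcommands.

## CLI

```bash
# simulate a sample from a karyotype YAML
her2snp simulate --spec karyotype.yaml --seed 1 --out probes.tsv --truth truth.json

# segment and call
her2snp segment --in probes.tsv --platform snp500k --out segments.seg
her2snp call --segments segments.seg --out call.json
her2snp ploidy --probes probes.tsv --segments segments.seg --purity 0.85 --out ploidy.json

# concordance analysis on the packaged clinical table
her2snp concordance --out report.json          # original IHC/FISH values
her2snp concordance --use-revised --out r.json # re-analysis values (samples 49/60/63)

# full pipeline (simulate -> segment -> call -> ploidy -> summary)
her2snp run --spec karyotype.yaml --seed 1 --out outdir/
```

Karyotype YAML schema (all fields optional except regions' coordinates):

```yaml
background: [2, 2]        # parental copy counts of the genome baseline
purity: 0.85              # tumor-cell fraction
noise_sd: 0.1             # intensity noise on the copy-number scale
baf_sd: 0.03              # allele-ratio noise
probes_per_mb: 4.0
het_fraction: 0.6
regions:
  - {chrom: "17", start: 26500001, end: 81195210, copies_a: 3, copies_b: 1}
```

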