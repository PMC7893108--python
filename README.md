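# snpstrmix

Interpretation toolkit for **SNP-STR compound markers** in unbalanced
two-person DNA mixtures, built for forensic geneticists who type trace
samples with SNP-allele-specific (ARMS) primers on a capillary
electrophoresis platform.

A SNP-STR is a biallelic SNP physically linked to an STR and amplified as a
single phased unit: the fluorophore of the allele-specific primer reads out
the SNP allele, the fragment size reads out the STR repeat number.  When the
major contributor of a heavily unbalanced mixture (for example a victim's
vaginal swab at 1:50–1:500) is homozygous for one SNP allele, the primer
specific to the *opposite* allele amplifies only the minor contributor —
peaks appear free of the major contributor's signal.

The package covers the full interpretation chain:

* **haplotype_model** — marker/haplotype/genotype types, `A11/C9` notation,
  haplotype- and SNP-class-frequency estimation from population surveys, and
  an NRC-II-style minimum-frequency floor (default 5/2N) for casework
  haplotypes absent from the survey.
* **informativeness** — the configuration theory for two contributors with
  SNP class frequencies M and N (M + N = 1): informative genotype 1 (both
  homozygous, opposite alleles; probability 2M²N²), informative genotype 2
  (major hom, minor het; 2M³N + 2MN³), informative genotype 3 (both
  homozygous for the same allele; M⁴ + N⁴ — a *peak-free* profile is the
  expected, and still evidential, outcome), and the uninformative case
  (major het; 2M³N + 4M²N² + 2MN³).  Panel aggregation: means, combined
  values 1 − ∏(1 − Iℓ), and exact binomial tails for hypothetical panels.
* **forensic_params** — match probability MP = Σ(genotype share)², power of
  discrimination PD = 1 − MP, cumulative MP/PD across loci, observed and
  Nei-unbiased expected heterozygosity, a seeded Monte-Carlo exact test of
  Hardy–Weinberg equilibrium (Guo–Thompson-style chromosome shuffling), and
  per-primer stutter statistics with the mean + 3 SD filter threshold.
* **lr_engine** — likelihood ratios for Hp (victim + suspect) versus Hd
  (victim + unknown HWE individual).  With target-class haplotype
  frequencies f(·) and non-target class total Q, the defence likelihood is
  2f(a)f(b), f(a)² + 2f(a)Q, or Q² for two, one, or zero observed alleles;
  per-locus LRs multiply across independent markers in log10 space.
* **simulator** — seeded HWE populations, two-person mixture scenarios
  (ratios 1:50–1:500, minor template 0.05 ng) and CE peak profiles with
  per-primer stutter (means 1.68 %–9.16 %), log-normal height noise,
  per-primer sensitivity classes (0.005–0.05 ng) and the 50 RFU analytical
  threshold, including a builtin 18-locus panel.
* **io_cli** — TSV/CSV readers and writers, case-report rendering, and the
  `snpstrmix` command line (`freqs`, `ivalues`, `expect`, `params`, `hwe`,
  `stutter`, `classify`, `lr`, `simulate`).

## Worked example

Simulate a 1:200 mixture case on the builtin panel with the suspect as the
true minor contributor, then evaluate it:

```python
from snpstrmix import *

panel = builtin_panel()
scenario = MixtureScenario(ratio=200.0, sensitivity=panel.sensitivity,
                           stutter_model=panel.stutter)
case = simulate_case(panel, scenario, truth="hp", seed=42)
report = analyze_case(case.victim, case.suspect, case.profiles, panel.frequencies)

print("combined LR = %.3g  (log10 = %.2f)" % (report.combined_lr,
                                              report.log10_combined_lr))
for cls in (ConfigurationClass.IG1, ConfigurationClass.IG2,
            ConfigurationClass.IG3, ConfigurationClass.UNINFORMATIVE):
    n = report.class_counts.get(cls, 0)
    avg = report.class_average_lr.get(cls)
    print(f"{cls.value:24s} n={n:2d}  average LR = "
          + (f"{avg:.3f}" if avg else "-"))
```

prints

```
combined LR = 6.86e+09  (log10 = 9.84)
informative genotype 1   n= 2  average LR = 86.125
informative genotype 2   n= 5  average LR = 26.101
informative genotype 3   n= 5  average LR = 1.247
uninformative genotype   n= 6  average LR = -
```

Twelve of the 18 loci were informative for this victim (SNP-homozygous);
each contributes an LR ≥ 1 because the true minor contributor is the
suspect, and the six loci where the victim is SNP-heterozygous carry no LR.
The same pipeline is available from the shell:

```sh
snpstrmix --seed 42 simulate --case --ratio 200 --truth hp --out sim/
snpstrmix lr --victim victim.csv --suspect suspect.csv \
             --trace sim/trace_peaks.csv --freqs sim/panel_frequencies.tsv \
             --out case_report/
```

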