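# Methods

## Markers and notation

A SNP-STR locus pairs a biallelic SNP with a nearby STR, typed as one phased
amplicon by allele-specific (ARMS) PCR.  A haplotype is written
`<SNP allele><STR repeats>` (`A11`, `C22.2`); a genotype is an unordered
haplotype pair, canonically ordered (SNP allele alphabetical, then STR
numeric) so homozygote detection, hashing and serialization are
deterministic.  STR alleles are exact decimal text labels compared through a
scaled-integer key in tenths of a repeat unit: `22.2 → 222`, and "one repeat
unit" is always a key difference of 10, including for microvariants.  This
avoids every floating-point pitfall of treating 22.2 as a float.

Haplotype frequencies are estimated by direct counting over 2n phased
chromosomes (ARMS typing yields phase by construction; no statistical
phasing exists anywhere in the package).  Missing genotypes are excluded
per locus, not per sample, following standard population-genetics practice.
A casework haplotype absent from the survey receives a minimum-frequency
floor before use in a likelihood: the default is the NRC-II-style 5/(2N),
with 1/(2N) and fixed numeric floors available; a fixed floor is mandatory
when a frequency table carries no chromosome count.

## Informativeness theory

For an ordered (major, minor) contributor pair drawn independently from a
Hardy–Weinberg population with SNP class frequencies M and N:

| configuration | condition | probability |
|---|---|---|
| informative genotype 1 | both SNP-homozygous, opposite alleles | 2M²N² |
| informative genotype 2 | major homozygous, minor heterozygous | 2M³N + 2MN³ |
| informative genotype 3 | both homozygous, same allele | M⁴ + N⁴ |
| uninformative | major heterozygous | 2M³N + 4M²N² + 2MN³ |

The four terms sum to (M + N)⁴ = 1 algebraically; the test suite checks this
identity and the equivalent 3×3 HWE genotype-table enumeration to 1e-12.
The locus informativeness I = 2M²N² + 2M³N + 2MN³ is the probability that
selective amplification of the minor contributor is possible at all.
Frequencies above 0.5 are accepted with a warning — the formulas are
symmetric in (M, N), so folded and unfolded inputs agree.

Panel projections assume independent markers.  The combined value is
1 − ∏(1 − Iℓ); counts of informative markers in a hypothetical panel of n
markers with common I use the exact binomial tail P(X ≥ k) via the
regularized incomplete beta function — no normal approximation, so the
k = 10, 11 tail cells of a 40-marker panel are exact rather than rounded to
zero.

## Forensic summary statistics

Match probability follows the Powerstats convention — the sum of squared
*observed* genotype proportions — rather than expected HWE genotype
frequencies; PD = 1 − MP, and multi-locus CMP/CPD are the product and its
complement.  Expected heterozygosity uses Nei's unbiased estimator
(2n/(2n−1))(1 − Σp²) on haplotype frequencies; observed heterozygosity is
the fraction of individuals whose two haplotypes differ.

The Hardy–Weinberg exact test is Monte-Carlo: the 2n observed chromosomes
are shuffled into n random diploid pairings (default 100 000 shuffles,
seeded NumPy generator, batched permutations), and p is the proportion of
shuffles whose conditional table probability — compared through the
statistic h·log 2 − Σ log n_g! with h the heterozygote count — is ≤ that of
the observed table, ties included.  Monomorphic loci return p = 1 by
convention.  The test suite validates against full enumeration of perfect
matchings at tiny n and calibrates the rejection rate under a simulated null
(50 diploids, five haplotypes at frequencies 0.30/0.25/0.20/0.15/0.10,
1 000 replicate datasets, 300 shuffles each) to fall in [0.03, 0.07] at
α = 0.05.

Stutter ratios are measured per allele-specific primer on single-source
profiles: parents are alleles called at the analytical threshold (50 RFU);
a candidate one repeat unit above or below a parent qualifies if its height
is ≥ 20 RFU and no more than half the parent height — the half-height guard
keeps a genuine adjacent allele of a balanced heterozygote from being
miscounted as stutter, which matters because stutter peaks themselves often
exceed the calling threshold.  The recommended filter is mean + 3 SD.  With
a single qualifying observation the SD is undefined and reported as 0 with
an explicit flag; a primer with no observations is absent from the result,
never reported as zero.

## Likelihood ratios

Hypotheses: Hp — the trace contributors are the victim and the suspect;
Hd — the victim and an unknown individual drawn by the product rule (HWE,
unrelated, no θ correction).  The victim must be SNP-homozygous for the
locus to be evaluated; the primer targets the opposite allele, so every
trace peak is attributable to the second contributor.

The detection model is deterministic — no dropout, no drop-in: a
contributor's target-class alleles are observed iff present.  P(E|Hp) is
then an indicator, and P(E|Hd) collapses from genotype enumeration to
closed forms with f(·) the target-class haplotype frequencies (floored if
unseen) and Q the non-target class total:

    P({a,b} | Hd) = 2 f(a) f(b)
    P({a}   | Hd) = f(a)² + 2 f(a) Q
    P({}    | Hd) = Q²

These satisfy Σ_O P(O|Hd) = 1 and the Turing identity E_Hd[LR] = 1, both
checked by enumeration and seeded Monte-Carlo in the test suite.  More than
two detected alleles imply an additional contributor; the engine refuses a
per-locus LR there and flags the locus rather than approximating.  Loci
where the victim is SNP-heterozygous carry no LR (reported "−", never
silently 1).  The combined LR is the product over defined per-locus LRs,
accumulated in log10 to avoid under/overflow, with per-class counts,
arithmetic-average LRs and products reported alongside.

A dropout-aware extension would replace the indicator numerator with a
per-allele detection probability; the hook exists in the deterministic
model's structure but is deliberately off — every validation quantity in
scope is reproduced without it, and the worked casework example's published
same-class cells differ from the closed forms by only ~0.2–0.3 %
(consistent with rounded published inputs), which the tests cover with a
2 % tolerance.

## Synthetic data

The builtin panel has 18 loci whose SNP minor-class frequencies equal the
reference population survey values (range 0.022–0.487).  Per-haplotype STR
spectra within each SNP class are *synthetic*: 4–7 repeat numbers drawn
from a plausible per-locus range with Dirichlet(1) weights, from a fixed
seed, because per-haplotype survey frequencies are not published in the
primary tables.  Consequences: class totals, configuration probabilities
and every class-level quantity are faithful to the survey; haplotype-level
quantities (e.g. per-locus MP) are realistic but not the survey's.

Peak rendering: expected allele height = gain × contributing template mass,
with gain 6 000 RFU/ng (so a 1 ng heterozygous reference yields ~3 000 RFU
peaks and a 0.05 ng minor-contributor allele ~150 RFU, comfortably above
the 50 RFU threshold); a homozygous target doses twice.  Heights are
jittered by a mean-one log-normal with CV 15 %.  Back-stutter appears one
repeat below each parent at a ratio drawn from Normal(mean, SD) truncated
at 0, with per-primer means spread deterministically over 1.68 %–9.16 %
(the two published anchor primers pinned to 1.68 % and 9.16 %, SD 0.01);
forward stutter is off by default.  A contributor whose template mass is
below the primer's sensitivity class (0.005/0.01/0.025/0.05 ng, encoded per
primer from the assay validation; the limit refers to total template
because the classes were established on heterozygous dilutions) drops out
entirely.  Peaks below the analytical threshold are removed.  Mixture
scenarios default to the validation design: ratios 1:50–1:500 with the
minor template fixed at 0.05 ng.

What the simulator does *not* emulate: electropherogram artifacts (pull-up,
−A adducts, spikes), degradation, PCR inhibition, primer competition in
multiplexes, and peak-height correlation between loci.  Passing recovery
and calibration tests therefore demonstrates internal consistency of the
estimators and the LR model under idealized CE behaviour, not robustness to
real-signal artifacts.

## Numerical choices and problem sizes

* Binomial tails via `scipy.stats.binom.sf` (regularized incomplete beta);
  cross-checked against a log-gamma summation oracle to 1e-10.
* LR combination in log10; products beyond the double range report the
  log10 value with an infinite linear-scale value.
* HWE Monte-Carlo ties counted as ≤ with a 1e-9 statistic tolerance;
  p-values are bit-reproducible given (data, mc_reps, seed).
* Frequency tables must sum to 1 ± 1e-6 on read; estimated tables satisfy
  1 ± 1e-9.  Floats serialize with `repr` for lossless round-trips; STR
  labels are preserved verbatim.
* Test-suite problem sizes: frequency recovery at n = 5 000 diploids
  (20 seeds, one 3σ exceedance tolerated across the ~10-haplotype joint
  check), configuration-class recovery at 50 000–100 000 pairs, Turing-mean
  checks at 15 000–20 000 Hd-true draws, stutter recovery at 500 profiles,
  HWE calibration at 1 000 datasets × 300 shuffles.  These sizes keep the
  whole suite around ten seconds while leaving Monte-Carlo standard errors
  well inside the asserted 3 SE bands.

## Known limitations

* Two contributors only; no suspect-absent or kinship propositions; no θ
  (subpopulation) correction; no continuous peak-height model.
* The uninformative configuration is detected and excluded, not modelled.
* The minimum-frequency floor is a pragmatic convention; likelihoods for
  observations containing unseen haplotypes depend on the chosen rule.
* Linkage disequilibrium between panel loci is assumed absent (combined LR
  multiplies per-locus values); the builtin panel treats all 18 loci as
  independent.
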