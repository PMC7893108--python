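"""Likelihood-ratio evaluation of allele-specific SNP-STR mixture profiles.

Scenario: a trace sample is an unbalanced two-person mixture; the major
contributor (typically the victim) and a suspect are both genotyped by
reference typing.  At every locus where the victim is SNP-homozygous, the
primer specific to the *opposite* SNP allele amplifies only haplotypes the
victim cannot contribute, so any peaks in the trace come from the second
contributor alone.

Hypotheses:

* Hp — the trace contributors are the victim and the suspect,
* Hd — the trace contributors are the victim and an unknown, unrelated
  individual drawn from the population by the product rule (HWE, no theta
  correction).

The detection model is deterministic (no dropout, no drop-in): a
contributor's target-class STR alleles are observed if and only if they are
present.  Under Hp the evidence probability is therefore an indicator; under
Hd it is obtained by enumerating the unknown's possible genotypes, which
collapses to closed forms over the target-class haplotype frequencies
f(.) and the non-target class total Q:

    observed {a, b} : 2 f(a) f(b)
    observed {a}    : f(a)^2 + 2 f(a) Q
    observed {}     : Q^2

Per-locus LRs multiply across independent markers (accumulated in log10
space); loci where the victim is SNP-heterozygous are uninformative and
carry no LR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .haplotype_model import (
    Genotype,
    Haplotype,
    LocusFrequencies,
    PeakProfile,
    SNPSTRLocus,
    SnpStrError,
)
from .informativeness import ConfigurationClass, classify_configuration

__all__ = [
    "ConfigurationError",
    "EvidenceImpossibleError",
    "PrimerSelection",
    "Observation",
    "CaseLocusResult",
    "CaseReport",
    "select_primer",
    "expected_peaks",
    "likelihood_unknown",
    "locus_lr",
    "combine",
    "analyze_case",
]


class ConfigurationError(SnpStrError, ValueError):
    """Case inputs are mutually inconsistent (e.g. wrong primer for victim)."""


class EvidenceImpossibleError(SnpStrError, ValueError):
    """The observed evidence has probability zero under the model."""


@dataclass(frozen=True)
class PrimerSelection:
    """The allele-specific primer used on the trace at one locus.

    Defined only when the victim is SNP-homozygous; the target is the SNP
    allele the victim does not carry.
    """

    locus: SNPSTRLocus
    target_snp_allele: str

    def __post_init__(self) -> None:
        if self.target_snp_allele not in self.locus.snp_alleles:
            raise ConfigurationError(
                f"primer target {self.target_snp_allele!r} is not an allele of "
                f"locus {self.locus.name}"
            )

    @property
    def primer_id(self) -> str:
        return self.locus.primer_id(self.target_snp_allele)


def select_primer(victim: Genotype) -> PrimerSelection | None:
    """Choose the informative primer given the victim's genotype.

    Victim SNP-homozygous for X -> primer targeting the opposite allele;
    victim SNP-heterozygous -> None (the locus is uninformative).
    """
    if not victim.is_snp_homozygous:
        return None
    present = victim.haplotypes[0].snp_allele
    return PrimerSelection(victim.locus, victim.locus.other_allele(present))


def expected_peaks(contributor: Genotype, primer: PrimerSelection) -> frozenset[str]:
    """STR alleles the primer would amplify from a contributor (no dropout)."""
    return frozenset(
        h.str_allele for h in contributor.haplotypes
        if h.snp_allele == primer.target_snp_allele
    )


@dataclass(frozen=True)
class Observation:
    """Trace evidence at one locus: the detected target-class STR alleles.

    A single further contributor can show 0, 1 or 2 distinct alleles; an
    empty set is a legal observation (expected whenever both contributors
    are homozygous for the primer's opposite allele).
    """

    locus: SNPSTRLocus
    primer: PrimerSelection
    detected_str_alleles: frozenset[str]

    def __post_init__(self) -> None:
        if self.primer.locus.name != self.locus.name:
            raise ConfigurationError(
                f"observation at {self.locus.name} made with a primer for "
                f"{self.primer.locus.name}"
            )
        if len(self.detected_str_alleles) > 2:
            raise ConfigurationError(
                f"locus {self.locus.name}: {len(self.detected_str_alleles)} detected "
                "alleles exceed what a single further contributor can explain"
            )


def likelihood_unknown(
    observation: Observation,
    freqs: LocusFrequencies,
    floor_rule: str | float = "five_over_2N",
) -> float:
    """P(evidence | the second contributor is an unknown HWE individual).

    Exhaustive enumeration over the unknown's genotypes reduces to closed
    forms in the target-class haplotype frequencies (floored when an
    observed haplotype is absent from the table) and the non-target class
    total Q.
    """
    target = observation.primer.target_snp_allele
    q = 1.0 - freqs.class_total(target)
    alleles = sorted(observation.detected_str_alleles)
    if not alleles:
        p = q * q
    else:
        f = [
            freqs.frequency(Haplotype(target, a), floor_rule=floor_rule)
            for a in alleles
        ]
        if len(alleles) == 2:
            p = 2.0 * f[0] * f[1]
        else:
            p = f[0] * f[0] + 2.0 * f[0] * q
    if p <= 0.0:
        raise EvidenceImpossibleError(
            f"locus {observation.locus.name}: observation {set(alleles) or '{}'} has zero "
            "probability under the defence model even after frequency flooring"
        )
    return p


@dataclass
class CaseLocusResult:
    """Outcome of the per-locus evaluation.

    ``lr`` is None for uninformative loci (victim SNP-heterozygous) and for
    loci excluded with a warning — never silently 1.
    """

    locus_name: str
    configuration: ConfigurationClass
    observation: Observation | None
    p_e_hp: float | None
    p_e_hd: float | None
    lr: float | None
    victim: Genotype | None = None
    suspect: Genotype | None = None
    warning: str | None = None


@dataclass
class CaseReport:
    """Panel-level aggregation of per-locus LR results."""

    results: list[CaseLocusResult]
    class_counts: dict[ConfigurationClass, int]
    class_average_lr: dict[ConfigurationClass, float]
    class_combined_lr: dict[ConfigurationClass, float]
    combined_lr: float
    log10_combined_lr: float
    n_informative: int


def locus_lr(
    victim: Genotype,
    suspect: Genotype,
    observation: Observation | None,
    freqs: LocusFrequencies,
    floor_rule: str | float = "five_over_2N",
) -> CaseLocusResult:
    """Evaluate one locus under Hp (victim + suspect) vs Hd (victim + unknown).

    P(E|Hp) is 1 when the suspect's target-class alleles equal the observed
    set and 0 otherwise (exclusion); P(E|Hd) comes from
    :func:`likelihood_unknown`.
    """
    configuration = classify_configuration(victim.snp_genotype, suspect.snp_genotype)
    primer = select_primer(victim)
    if primer is None:
        if observation is not None:
            raise ConfigurationError(
                f"locus {victim.locus.name}: the victim is SNP-heterozygous, no "
                "allele-specific typing of the trace is interpretable"
            )
        return CaseLocusResult(
            locus_name=victim.locus.name,
            configuration=configuration,
            observation=None,
            p_e_hp=None,
            p_e_hd=None,
            lr=None,
            victim=victim,
            suspect=suspect,
        )
    if observation is None:
        raise ConfigurationError(
            f"locus {victim.locus.name}: informative locus lacks a trace observation"
        )
    if observation.primer.target_snp_allele != primer.target_snp_allele:
        raise ConfigurationError(
            f"locus {victim.locus.name}: trace typed with the "
            f"{observation.primer.target_snp_allele}-primer but the victim's genotype "
            f"calls for the {primer.target_snp_allele}-primer"
        )
    p_hp = 1.0 if expected_peaks(suspect, primer) == observation.detected_str_alleles else 0.0
    p_hd = likelihood_unknown(observation, freqs, floor_rule=floor_rule)
    return CaseLocusResult(
        locus_name=victim.locus.name,
        configuration=configuration,
        observation=observation,
        p_e_hp=p_hp,
        p_e_hd=p_hd,
        lr=p_hp / p_hd,
        victim=victim,
        suspect=suspect,
    )


_INFORMATIVE_CLASSES = (
    ConfigurationClass.IG1,
    ConfigurationClass.IG2,
    ConfigurationClass.IG3,
)


def combine(results: Sequence[CaseLocusResult]) -> CaseReport:
    """Aggregate per-locus results into the case-level report.

    The combined LR is the product of all defined per-locus LRs (markers
    assumed independent), accumulated in log10 space; per configuration
    class the report carries the count, arithmetic-average LR and product.
    """
    defined = [r for r in results if r.lr is not None]
    if not defined:
        raise ValueError("no locus has a defined LR; nothing to combine")
    class_counts: dict[ConfigurationClass, int] = {}
    for r in results:
        class_counts[r.configuration] = class_counts.get(r.configuration, 0) + 1
    class_avg: dict[ConfigurationClass, float] = {}
    class_comb: dict[ConfigurationClass, float] = {}
    for cls_ in _INFORMATIVE_CLASSES:
        lrs = [r.lr for r in defined if r.configuration is cls_]
        if lrs:
            class_avg[cls_] = sum(lrs) / len(lrs)
            class_comb[cls_] = _product_log10(lrs)[0]
    combined, log10_combined = _product_log10([r.lr for r in defined])
    return CaseReport(
        results=list(results),
        class_counts=class_counts,
        class_average_lr=class_avg,
        class_combined_lr=class_comb,
        combined_lr=combined,
        log10_combined_lr=log10_combined,
        n_informative=len(defined),
    )


def _product_log10(values: Sequence[float]) -> tuple[float, float]:
    """Product of non-negative values via log10 accumulation."""
    if any(v == 0.0 for v in values):
        return 0.0, float("-inf")
    log10 = sum(math.log10(v) for v in values)
    value = 10.0 ** log10 if log10 < 308 else math.inf  # report inf past float range
    return value, log10


def analyze_case(
    victim_genotypes: Mapping[str, Genotype],
    suspect_genotypes: Mapping[str, Genotype],
    trace_profiles: Iterable[PeakProfile],
    freqs: Mapping[str, LocusFrequencies],
    analytical_threshold: float = 50.0,
    floor_rule: str | float = "five_over_2N",
) -> CaseReport:
    """Full casework pipeline over a panel.

    For each locus of the victim's reference profile: select the informative
    primer from the victim's SNP genotype, extract the observation from the
    trace profile (alleles called at the analytical threshold, default
    50 RFU), and evaluate the per-locus LR; finally combine.  A trace
    profile typed with a primer inconsistent with the victim is a
    configuration error.  A locus showing more than two detected alleles
    (extra contributor) is flagged and excluded with a warning.  An
    informative locus with no trace profile on file is interpreted as a
    typed, peak-free observation.
    """
    profile_index: dict[tuple[str, str], PeakProfile] = {}
    for p in trace_profiles:
        profile_index[(p.locus_name, p.primer_snp_allele)] = p
    results: list[CaseLocusResult] = []
    for locus_name, victim in victim_genotypes.items():
        if locus_name not in suspect_genotypes:
            raise ConfigurationError(f"suspect reference profile lacks locus {locus_name}")
        suspect = suspect_genotypes[locus_name]
        primer = select_primer(victim)
        if primer is None:
            # any trace typing at this locus used an uninterpretable primer
            for allele in victim.locus.snp_alleles:
                if (locus_name, allele) in profile_index:
                    raise ConfigurationError(
                        f"locus {locus_name}: trace typed with the {allele}-primer but "
                        "the victim is SNP-heterozygous (uninformative locus)"
                    )
            results.append(locus_lr(victim, suspect, None, freqs[locus_name],
                                    floor_rule=floor_rule))
            continue
        wrong = (locus_name, victim.haplotypes[0].snp_allele)
        if wrong in profile_index:
            raise ConfigurationError(
                f"locus {locus_name}: trace typed with the {wrong[1]}-primer, which the "
                "victim also amplifies; expected the "
                f"{primer.target_snp_allele}-primer"
            )
        profile = profile_index.get((locus_name, primer.target_snp_allele))
        detected = (
            frozenset(profile.called_alleles(analytical_threshold)) if profile else frozenset()
        )
        if len(detected) > 2:
            msg = (
                f"locus {locus_name}: {len(detected)} alleles detected; a two-person "
                "mixture model cannot explain extra minor alleles — locus excluded"
            )
            warnings.warn(msg, stacklevel=2)
            results.append(
                CaseLocusResult(
                    locus_name=locus_name,
                    configuration=classify_configuration(
                        victim.snp_genotype, suspect.snp_genotype
                    ),
                    observation=None,
                    p_e_hp=None,
                    p_e_hd=None,
                    lr=None,
                    victim=victim,
                    suspect=suspect,
                    warning=msg,
                )
            )
            continue
        observation = Observation(victim.locus, primer, detected)
        results.append(
            locus_lr(victim, suspect, observation, freqs[locus_name], floor_rule=floor_rule)
        )
    return combine(results)
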