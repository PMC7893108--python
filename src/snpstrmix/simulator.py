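"""Synthetic SNP-STR data generator.

Produces Hardy-Weinberg populations, two-person unbalanced-mixture cases,
and allele-specific-primer CE peak profiles with stutter, multiplicative
noise, per-primer sensitivity limits, and the analytical calling threshold —
enough to exercise every estimation and interpretation code path without any
external data.

The builtin 18-locus panel carries the observed SNP minor-class frequencies
of the reference population survey; the STR allele spectrum inside each SNP
class is synthetic (Dirichlet-weighted over a plausible repeat-number range,
fixed seed), since per-haplotype population frequencies are not published in
the primary tables.  Per-primer PCR sensitivity classes (0.005-0.05 ng
minimum template) and mixture-ratio capabilities follow the reported assay
validation; stutter means span the reported 1.68 %-9.16 % range with the two
anchor primers fixed at their published values.

Peak-height mechanics (gain, log-normal noise) are deliberately simple
plumbing: expected allele height is proportional to the contributing
template mass (a homozygous target doses twice), a mean-one log-normal
factor models amplification noise, back-stutter appears one repeat below
each parent at a truncated-normal ratio, and peaks below the analytical
threshold are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .haplotype_model import (
    Genotype,
    Haplotype,
    LocusFrequencies,
    Peak,
    PeakProfile,
    PopulationSample,
    SNPSTRLocus,
    str_allele_key,
)
from .informativeness import ConfigurationClass, classify_configuration
from .lr_engine import PrimerSelection, select_primer

__all__ = [
    "PanelSpec",
    "MixtureScenario",
    "SimulatedCase",
    "builtin_panel",
    "simulate_population",
    "simulate_case",
    "render_peaks",
]


def str_allele_label(key: int) -> str:
    """Inverse of :func:`str_allele_key`: 110 -> "11", 222 -> "22.2"."""
    whole, frac = divmod(key, 10)
    return str(whole) if frac == 0 else f"{whole}.{frac}"


@dataclass
class PanelSpec:
    """A panel of SNP-STR loci with frequencies and per-primer assay metadata."""

    loci: list[SNPSTRLocus]
    frequencies: dict[str, LocusFrequencies]
    stutter: dict[str, tuple[float, float]] = field(default_factory=dict)  # primer -> (mean, sd)
    sensitivity: dict[str, float] = field(default_factory=dict)  # primer -> min template ng
    mixture_limit: dict[str, int] = field(default_factory=dict)  # primer -> max tested ratio

    def locus(self, name: str) -> SNPSTRLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def loci_by_name(self) -> dict[str, SNPSTRLocus]:
        return {l.name: l for l in self.loci}


@dataclass
class MixtureScenario:
    """Conditions of a simulated two-person unbalanced mixture.

    ``ratio`` is major:minor (500 means 1:500 with the minor as trace
    target); the minor template defaults to the 0.05 ng used throughout the
    mixture validation series; thresholds are the 50 RFU analytical and
    20 RFU stutter constants.  ``sensitivity`` and ``stutter_model`` may be
    scalars/tuples (applied to every primer) or per-primer maps.
    """

    ratio: float = 500.0
    minor_template_ng: float = 0.05
    analytical_threshold: float = 50.0
    stutter_height_min: float = 20.0
    gain_rfu_per_ng: float = 6000.0
    noise_cv: float = 0.15
    forward_stutter: bool = False
    sensitivity: float | Mapping[str, float] = 0.025
    stutter_model: tuple[float, float] | Mapping[str, tuple[float, float]] = (0.05, 0.01)

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("mixture ratio must be >= 1 (major:minor)")
        if self.minor_template_ng <= 0:
            raise ValueError("minor template mass must be positive")
        if self.analytical_threshold <= 0 or self.stutter_height_min <= 0:
            raise ValueError("thresholds must be positive")

    def sensitivity_for(self, primer_id: str) -> float:
        if isinstance(self.sensitivity, Mapping):
            return self.sensitivity.get(primer_id, 0.025)
        return float(self.sensitivity)

    def stutter_for(self, primer_id: str) -> tuple[float, float]:
        if isinstance(self.stutter_model, Mapping):
            return self.stutter_model.get(primer_id, (0.05, 0.01))
        return self.stutter_model


# (snp_id, str_name, (allele, allele), minor_allele, minor_class_freq,
#  STR repeat range within which the synthetic spectrum is drawn)
_PANEL18 = [
    ("rs11642858", "D16S539", ("A", "C"), "C", 0.447, (8, 15)),
    ("rs58390469", "D2S441", ("A", "C"), "C", 0.478, (9, 16)),
    ("rs2325399", "D6S1043", ("C", "G"), "G", 0.3982, (11, 21)),
    ("rs2070018", "FGA", ("C", "T"), "C", 0.097, (18, 26)),
    ("rs25768", "D5S818", ("A", "G"), "A", 0.062, (7, 13)),
    ("rs9531308", "D13S317", ("A", "C"), "C", 0.469, (8, 15)),
    ("rs8031604", "Penta E", ("G", "T"), "T", 0.058, (10, 21)),
    ("rs4847015", "D1S1656", ("C", "T"), "T", 0.128, (11, 18)),
    ("rs7962284", "D12S391", ("C", "T"), "C", 0.305, (15, 24)),
    ("rs7275705", "Penta D", ("C", "G"), "G", 0.2552, (8, 15)),
    ("rs7786079", "D7S820", ("A", "C"), "C", 0.022, (7, 13)),
    ("rs57346531", "D8S1179", ("A", "G"), "G", 0.3142, (10, 17)),
    ("rs2246512", "D10S1248", ("A", "G"), "G", 0.3142, (11, 17)),
    ("rs17077990", "D3S1358", ("C", "G"), "G", 0.19, (12, 19)),
    ("rs17651965", "CSF1PO", ("C", "G"), "G", 0.407, (9, 14)),
    ("rs6736691", "D2S1338", ("A", "C"), "A", 0.093, (16, 25)),
    ("rs13413321", "TPOX", ("G", "T"), "G", 0.487, (6, 12)),
    ("rs9362476", "SE33", ("C", "T"), "T", 0.385, (14, 30)),
]

# minimum template (ng) for a positive single-source profile, per primer;
# primers not listed fall in the 0.025 ng class
_SENSITIVITY = {
    "rs11642858C-D16S539": 0.005,
    "rs17077990G-D3S1358": 0.005,
    "rs2070018C-FGA": 0.01,
    "rs25768A-D5S818": 0.01,
    "rs4847015T-D1S1656": 0.01,
    "rs7962284C-D12S391": 0.01,
    "rs7786079C-D7S820": 0.01,
    "rs2246512G-D10S1248": 0.01,
    "rs6736691A-D2S1338": 0.01,
    "rs58390469C-D2S441": 0.01,
    "rs2325399G-D6S1043": 0.01,
    "rs9531308C-D13S317": 0.05,
    "rs7962284T-D12S391": 0.05,
    "rs7275705C-Penta D": 0.05,
    "rs7786079A-D7S820": 0.05,
    "rs57346531A-D8S1179": 0.05,
    "rs2246512A-D10S1248": 0.05,
    "rs6736691C-D2S1338": 0.05,
    "rs9362476T-SE33": 0.05,
}

# deepest major:minor ratio at which the primer resolved the minor
# contributor in the mixture validation; unvalidated primers default to 500
_MIXTURE_LIMIT = {
    "rs4847015C-D1S1656": 200,
    "rs7962284T-D12S391": 200,
    "rs2246512G-D10S1248": 200,
    "rs9362476C-SE33": 100,
    "rs25768A-D5S818": 100,
    "rs2070018T-FGA": 50,
}

# published anchors of the per-primer mean stutter-ratio range
_STUTTER_ANCHORS = {
    "rs58390469A-D2S441": 0.0168,
    "rs7962284C-D12S391": 0.0916,
}


def builtin_panel(str_spectrum_seed: int = 1331175) -> PanelSpec:
    """The default 18-locus SNP-STR panel.

    SNP class frequencies are the observed survey values; STR spectra within
    each class are synthetic Dirichlet draws, reproducible from
    ``str_spectrum_seed``.
    """
    rng = np.random.default_rng(str_spectrum_seed)
    loci: list[SNPSTRLocus] = []
    frequencies: dict[str, LocusFrequencies] = {}
    primer_ids: list[str] = []
    for snp_id, str_name, alleles, minor, maf, (lo, hi) in _PANEL18:
        locus = SNPSTRLocus(
            name=f"{snp_id}-{str_name}", snp_id=snp_id, str_name=str_name, snp_alleles=alleles
        )
        loci.append(locus)
        primer_ids.extend(locus.primer_id(a) for a in alleles)
        hap_freqs: dict[Haplotype, float] = {}
        for allele in alleles:
            class_freq = maf if allele == minor else 1.0 - maf
            n_alleles = int(rng.integers(4, min(7, hi - lo + 1) + 1))
            repeats = sorted(rng.choice(np.arange(lo, hi + 1), size=n_alleles, replace=False))
            weights = rng.dirichlet(np.ones(n_alleles))
            for rep, w in zip(repeats, weights):
                hap_freqs[Haplotype(allele, str(int(rep)))] = float(w * class_freq)
        # renormalize away float dust so the container invariant holds tightly
        total = sum(hap_freqs.values())
        hap_freqs = {h: f / total for h, f in hap_freqs.items()}
        frequencies[locus.name] = LocusFrequencies(
            locus=locus, haplotype_freqs=hap_freqs, chromosome_count=226
        )
    # mean stutter ratios spread deterministically over the observed range,
    # with the two published anchor primers pinned
    means = np.linspace(0.0168, 0.0916, num=len(primer_ids))
    stutter = {pid: (float(m), 0.01) for pid, m in zip(sorted(primer_ids), means)}
    stutter.update({pid: (m, 0.01) for pid, m in _STUTTER_ANCHORS.items()})
    sensitivity = {pid: _SENSITIVITY.get(pid, 0.025) for pid in primer_ids}
    mixture_limit = {pid: _MIXTURE_LIMIT.get(pid, 500) for pid in primer_ids}
    return PanelSpec(
        loci=loci,
        frequencies=frequencies,
        stutter=stutter,
        sensitivity=sensitivity,
        mixture_limit=mixture_limit,
    )


def _draw_genotype(
    locus: SNPSTRLocus, freqs: LocusFrequencies, rng: np.random.Generator
) -> Genotype:
    haps = list(freqs.haplotype_freqs)
    probs = np.array([freqs.haplotype_freqs[h] for h in haps])
    i, j = rng.choice(len(haps), size=2, p=probs)
    return Genotype(locus, (haps[i], haps[j]))


def simulate_population(panel: PanelSpec, n: int, seed: int = 0) -> PopulationSample:
    """Draw n diploid individuals, each locus two independent haplotype draws."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    genotypes: dict[str, dict[str, Genotype]] = {}
    for idx in range(n):
        sid = f"S{idx + 1:05d}"
        genotypes[sid] = {}
    for locus in panel.loci:
        freqs = panel.frequencies[locus.name]
        haps = list(freqs.haplotype_freqs)
        probs = np.array([freqs.haplotype_freqs[h] for h in haps])
        draws = rng.choice(len(haps), size=(n, 2), p=probs)
        for idx, (i, j) in enumerate(draws):
            sid = f"S{idx + 1:05d}"
            genotypes[sid][locus.name] = Genotype(locus, (haps[i], haps[j]))
    return PopulationSample(genotypes=genotypes)


def render_peaks(
    contributors: Sequence[tuple[Genotype, float]],
    primer: PrimerSelection,
    scenario: MixtureScenario,
    rng: np.random.Generator,
    sample_id: str = "trace",
) -> PeakProfile:
    """Simulate the CE profile of one allele-specific PCR on a mixed template.

    ``contributors`` pairs each genotype with its template mass in ng.  Only
    target-class haplotypes amplify; a contributor whose target-class
    template falls below the primer's sensitivity drops out entirely.
    Allelic expected height = gain x allele mass (x2 dose for a homozygous
    target), jittered by a mean-one log-normal with the configured CV.
    Back-stutter appears one repeat below each parent at a ratio drawn from
    a normal truncated at zero; optional forward stutter sits one repeat
    above.  Peaks below the analytical threshold are removed.
    """
    primer_id = primer.primer_id
    sensitivity = scenario.sensitivity_for(primer_id)
    stutter_mean, stutter_sd = scenario.stutter_for(primer_id)
    sigma = float(np.sqrt(np.log(1.0 + scenario.noise_cv**2)))
    expected_mass: dict[int, float] = {}
    for genotype, mass in contributors:
        if mass <= 0:
            raise ValueError("contributor template mass must be positive")
        target_haps = [
            h for h in genotype.haplotypes if h.snp_allele == primer.target_snp_allele
        ]
        # sensitivity classes were established on heterozygous single-source
        # dilutions, so the limit refers to the contributor's total template
        if not target_haps or mass < sensitivity:
            continue  # below the primer's detection capability: full dropout
        for h in target_haps:
            key = str_allele_key(h.str_allele)
            expected_mass[key] = expected_mass.get(key, 0.0) + mass / 2.0
    heights: dict[int, float] = {}
    for key in sorted(expected_mass):
        noise = float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))
        heights[key] = scenario.gain_rfu_per_ng * expected_mass[key] * noise
    # stutter of each allelic parent
    for key in sorted(list(heights)):
        parent_height = heights[key]
        positions = [key - 10] + ([key + 10] if scenario.forward_stutter else [])
        for pos in positions:
            ratio = max(0.0, float(rng.normal(stutter_mean, stutter_sd)))
            if ratio <= 0.0:
                continue
            heights[pos] = heights.get(pos, 0.0) + ratio * parent_height
    peaks = [
        Peak(str_allele=str_allele_label(key), height=round(h, 1))
        for key, h in sorted(heights.items())
        if h >= scenario.analytical_threshold
    ]
    return PeakProfile(
        sample_id=sample_id,
        locus_name=primer.locus.name,
        primer_snp_allele=primer.target_snp_allele,
        peaks=peaks,
    )


@dataclass
class SimulatedCase:
    """Ground truth and trace evidence of one simulated two-person case."""

    truth: str  # "hp" (suspect is the minor contributor) or "hd"
    victim: dict[str, Genotype]
    suspect: dict[str, Genotype]
    true_minor: dict[str, Genotype]
    profiles: list[PeakProfile]


def simulate_case(
    panel: PanelSpec,
    scenario: MixtureScenario,
    truth: str = "hp",
    seed: int = 0,
    condition_class: ConfigurationClass | None = None,
) -> SimulatedCase:
    """Simulate a two-person mixture case over the panel.

    The victim (major) and the true minor contributor are population draws;
    under ``truth="hp"`` the suspect *is* the minor contributor, under
    ``"hd"`` the suspect is an independent draw.  ``condition_class``
    optionally resamples each locus until the (victim, minor) SNP
    configuration matches (e.g. IG2: major homozygous, minor heterozygous,
    as in the mixture validation design); loci where the condition is
    unattainable are skipped with a warning.  Trace profiles are rendered
    for every informative primer.
    """
    if truth not in ("hp", "hd"):
        raise ValueError("truth must be 'hp' or 'hd'")
    rng = np.random.default_rng(seed)
    victim: dict[str, Genotype] = {}
    minor: dict[str, Genotype] = {}
    suspect: dict[str, Genotype] = {}
    profiles: list[PeakProfile] = []
    major_mass = scenario.minor_template_ng * scenario.ratio
    for locus in panel.loci:
        freqs = panel.frequencies[locus.name]
        v = m = None
        for _ in range(10_000):
            v = _draw_genotype(locus, freqs, rng)
            m = _draw_genotype(locus, freqs, rng)
            if condition_class is None:
                break
            if classify_configuration(v.snp_genotype, m.snp_genotype) is condition_class:
                break
        else:
            warnings.warn(
                f"locus {locus.name}: configuration {condition_class} not attainable, "
                "locus skipped",
                stacklevel=2,
            )
            continue
        victim[locus.name] = v
        minor[locus.name] = m
        suspect[locus.name] = m if truth == "hp" else _draw_genotype(locus, freqs, rng)
        primer = select_primer(v)
        if primer is not None:
            profiles.append(
                render_peaks(
                    [(v, major_mass), (m, scenario.minor_template_ng)],
                    primer,
                    scenario,
                    rng,
                )
            )
    return SimulatedCase(
        truth=truth, victim=victim, suspect=suspect, true_minor=minor, profiles=profiles
    )
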