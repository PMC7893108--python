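"""Core domain types for SNP-STR compound markers.

A SNP-STR marker is a biallelic SNP physically linked to an STR, typed as a
single phased unit by allele-specific (ARMS) PCR: each amplification product
carries both the SNP allele (fluorophore colour) and the STR repeat number
(fragment size), so haplotypes are observed directly — no statistical phasing
is involved.

This module defines the marker/haplotype/genotype containers, parsing of the
conventional ``A11/C9`` haplotype-pair notation, estimation of haplotype and
SNP-class frequencies from population genotype tables, and the minimum-
frequency floor applied to casework haplotypes that are absent from the
population survey.

STR alleles are kept as exact decimal text labels ("11", "22.2") and compared
through a scaled-integer key (tenths of a repeat unit), so microvariant
labels never suffer floating-point drift and "one repeat unit" is always a
key difference of 10.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "SnpStrError",
    "GenotypeParseError",
    "FrequencyError",
    "str_allele_key",
    "SNPSTRLocus",
    "Haplotype",
    "Genotype",
    "parse_genotype",
    "PopulationSample",
    "LocusFrequencies",
    "estimate_frequencies",
    "apply_frequency_floor",
    "Peak",
    "PeakProfile",
]


class SnpStrError(Exception):
    """Base class for all package-specific errors."""


class GenotypeParseError(SnpStrError, ValueError):
    """A haplotype-pair string could not be parsed at a locus."""


class FrequencyError(SnpStrError, ValueError):
    """Invalid or inconsistent haplotype frequency data."""


_STR_LABEL_RE = re.compile(r"^\d+(?:\.\d)?$")


def str_allele_key(label: str) -> int:
    """Return the numeric sort key of an STR allele label, in tenths of a repeat.

    ``"11" -> 110``, ``"22.2" -> 222``.  Parent/stutter positions one repeat
    unit apart always differ by exactly 10 in key space, including for
    microvariant alleles (21.2 is one repeat below 22.2).
    """
    if not _STR_LABEL_RE.match(label):
        raise GenotypeParseError(f"invalid STR allele label {label!r}")
    if "." in label:
        whole, frac = label.split(".")
        return int(whole) * 10 + int(frac)
    return int(label) * 10


@dataclass(frozen=True)
class SNPSTRLocus:
    """A compound SNP-STR marker: one biallelic SNP linked to one STR.

    ``name`` follows the ``<snp_id>-<str_name>`` convention, e.g.
    ``rs58390469-D2S441``; ``snp_alleles`` is the ordered pair of the SNP's
    two single-base alleles.
    """

    name: str
    snp_id: str
    str_name: str
    snp_alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.snp_alleles
        if a == b:
            raise ValueError(f"locus {self.name}: SNP alleles must be distinct, got {a!r} twice")
        for x in (a, b):
            if len(x) != 1 or not x.isalpha():
                raise ValueError(f"locus {self.name}: invalid SNP allele symbol {x!r}")

    @classmethod
    def from_name(cls, name: str, snp_alleles: tuple[str, str]) -> "SNPSTRLocus":
        """Build a locus from a ``rsXXXX-STRNAME`` identifier."""
        snp_id, _, str_name = name.partition("-")
        if not str_name:
            raise ValueError(f"locus name {name!r} is not of the form <snp_id>-<str_name>")
        return cls(name=name, snp_id=snp_id, str_name=str_name, snp_alleles=snp_alleles)

    def other_allele(self, snp_allele: str) -> str:
        """The SNP allele opposite to ``snp_allele`` at this locus."""
        a, b = self.snp_alleles
        if snp_allele == a:
            return b
        if snp_allele == b:
            return a
        raise ValueError(f"SNP allele {snp_allele!r} not defined at locus {self.name}")

    def primer_id(self, snp_allele: str) -> str:
        """Allele-specific-primer identifier, e.g. ``rs7962284C-D12S391``."""
        if snp_allele not in self.snp_alleles:
            raise ValueError(f"SNP allele {snp_allele!r} not defined at locus {self.name}")
        return f"{self.snp_id}{snp_allele}-{self.str_name}"


@dataclass(frozen=True, order=True)
class Haplotype:
    """One phased SNP-STR haplotype: a SNP allele paired with an STR allele label."""

    snp_allele: str
    str_allele: str

    def __post_init__(self) -> None:
        if len(self.snp_allele) != 1 or not self.snp_allele.isalpha():
            raise ValueError(f"invalid SNP allele symbol {self.snp_allele!r}")
        str_allele_key(self.str_allele)  # validates the label

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.snp_allele, str_allele_key(self.str_allele))

    def __str__(self) -> str:  # "A11", "C22.2"
        return f"{self.snp_allele}{self.str_allele}"


def _canonical_pair(h1: Haplotype, h2: Haplotype) -> tuple[Haplotype, Haplotype]:
    return tuple(sorted((h1, h2), key=lambda h: h.sort_key))  # type: ignore[return-value]


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of haplotypes at one locus, stored in canonical order.

    Canonical order is SNP allele alphabetical, then STR allele numeric
    ascending, so equality, hashing and serialization are deterministic.
    """

    locus: SNPSTRLocus
    haplotypes: tuple[Haplotype, Haplotype]

    def __post_init__(self) -> None:
        h1, h2 = self.haplotypes
        for h in (h1, h2):
            if h.snp_allele not in self.locus.snp_alleles:
                raise ValueError(
                    f"haplotype {h} carries SNP allele {h.snp_allele!r} "
                    f"not defined at locus {self.locus.name}"
                )
        object.__setattr__(self, "haplotypes", _canonical_pair(h1, h2))

    @property
    def snp_genotype(self) -> tuple[str, str]:
        """The SNP-only genotype as a sorted allele pair."""
        return tuple(sorted(h.snp_allele for h in self.haplotypes))  # type: ignore[return-value]

    @property
    def is_snp_homozygous(self) -> bool:
        return self.haplotypes[0].snp_allele == self.haplotypes[1].snp_allele

    @property
    def is_heterozygous(self) -> bool:
        """Haplotype-level heterozygosity: the two haplotypes differ."""
        return self.haplotypes[0] != self.haplotypes[1]

    def __str__(self) -> str:
        return f"{self.haplotypes[0]}/{self.haplotypes[1]}"


_GENOTYPE_RE = re.compile(
    r"^\s*([A-Za-z])(\d+(?:\.\d)?)\s*[/-]\s*([A-Za-z])(\d+(?:\.\d)?)\s*$"
)


def parse_genotype(text: str, locus: SNPSTRLocus) -> Genotype:
    """Parse a haplotype-pair string like ``"A11-A14"`` or ``"C9/A11"``.

    Both ``-`` and ``/`` separators are accepted; the canonical form on
    output is ``/``.  The SNP symbols must belong to ``locus.snp_alleles``.
    """
    m = _GENOTYPE_RE.match(text)
    if not m:
        raise GenotypeParseError(
            f"locus {locus.name}: cannot parse genotype string {text!r} "
            f"(expected e.g. 'A11/C9' or 'A11-C9')"
        )
    s1, r1, s2, r2 = m.groups()
    for s in (s1, s2):
        if s not in locus.snp_alleles:
            raise GenotypeParseError(
                f"locus {locus.name}: SNP symbol {s!r} in token {text!r} is not one of "
                f"{locus.snp_alleles}"
            )
    return Genotype(locus, (Haplotype(s1, r1), Haplotype(s2, r2)))


@dataclass
class PopulationSample:
    """Genotypes of n diploid individuals over a panel of loci.

    ``genotypes`` maps sample id -> {locus name -> Genotype}; missing
    genotypes are simply absent from the inner map and are excluded
    per-locus from all counts.
    """

    genotypes: dict[str, dict[str, Genotype]]

    @property
    def sample_count(self) -> int:
        return len(self.genotypes)

    def genotypes_at(self, locus_name: str) -> list[Genotype]:
        """All genotypes typed at a locus, per-locus missing-data exclusion."""
        return [
            per_locus[locus_name]
            for per_locus in self.genotypes.values()
            if locus_name in per_locus
        ]


@dataclass
class LocusFrequencies:
    """Per-locus haplotype frequency distribution with derived SNP-class totals.

    ``chromosome_count`` is the 2n used for estimation (0 when the table was
    supplied externally without counts); it drives the minimum-frequency
    floor for unseen haplotypes.
    """

    locus: SNPSTRLocus
    haplotype_freqs: dict[Haplotype, float]
    chromosome_count: int = 0

    def __post_init__(self) -> None:
        if not self.haplotype_freqs:
            raise FrequencyError(f"locus {self.locus.name}: empty frequency table")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise FrequencyError(
                f"locus {self.locus.name}: haplotype frequencies sum to {total!r}, not 1"
            )
        for h, f in self.haplotype_freqs.items():
            if f < 0 or f > 1:
                raise FrequencyError(f"locus {self.locus.name}: frequency of {h} is {f!r}")
            if h.snp_allele not in self.locus.snp_alleles:
                raise FrequencyError(
                    f"locus {self.locus.name}: haplotype {h} has SNP allele outside "
                    f"{self.locus.snp_alleles}"
                )

    @property
    def snp_class_freqs(self) -> dict[str, float]:
        """Total frequency of each SNP allele class (M and N; M + N = 1)."""
        out = {a: 0.0 for a in self.locus.snp_alleles}
        for h, f in self.haplotype_freqs.items():
            out[h.snp_allele] += f
        return out

    def class_total(self, snp_allele: str) -> float:
        """Total frequency of one SNP allele class."""
        if snp_allele not in self.locus.snp_alleles:
            raise ValueError(f"SNP allele {snp_allele!r} not defined at locus {self.locus.name}")
        return self.snp_class_freqs[snp_allele]

    @property
    def maf(self) -> float:
        """The SNP minor-allele (class) frequency, min(M, N)."""
        return min(self.snp_class_freqs.values())

    def haplotypes_in_class(self, snp_allele: str) -> list[Haplotype]:
        return [h for h in self.haplotype_freqs if h.snp_allele == snp_allele]

    def frequency(self, haplotype: Haplotype, floor_rule: str | float = "five_over_2N") -> float:
        """Frequency of ``haplotype`` with the minimum-frequency floor applied."""
        return apply_frequency_floor(self, haplotype, floor_rule)


def estimate_frequencies(sample: PopulationSample, locus: SNPSTRLocus) -> LocusFrequencies:
    """Estimate haplotype frequencies at ``locus`` by direct counting.

    Every fully-typed individual contributes two phased chromosomes;
    frequency = count / (2 * typed n).
    """
    genotypes = sample.genotypes_at(locus.name)
    if not genotypes:
        raise FrequencyError(f"locus {locus.name}: no typed samples, cannot estimate frequencies")
    counts: dict[Haplotype, int] = {}
    for g in genotypes:
        if g.locus.name != locus.name:
            raise FrequencyError(f"genotype {g} does not belong to locus {locus.name}")
        for h in g.haplotypes:
            counts[h] = counts.get(h, 0) + 1
    two_n = 2 * len(genotypes)
    freqs = {h: c / two_n for h, c in sorted(counts.items(), key=lambda kv: kv[0].sort_key)}
    return LocusFrequencies(locus=locus, haplotype_freqs=freqs, chromosome_count=two_n)


def parse_floor_rule(rule: str | float) -> str | float:
    """Normalize a floor-rule spec: named rule, number, or ``"fixed:<x>"``."""
    if isinstance(rule, (int, float)):
        return float(rule)
    if rule in ("five_over_2N", "one_over_2N"):
        return rule
    if rule.startswith("fixed:"):
        return float(rule.split(":", 1)[1])
    raise ValueError(
        f"unknown frequency floor rule {rule!r} "
        "(expected 'five_over_2N', 'one_over_2N', 'fixed:<x>' or a number)"
    )


def apply_frequency_floor(
    freqs: LocusFrequencies, haplotype: Haplotype, floor_rule: str | float = "five_over_2N"
) -> float:
    """Return the stored frequency of ``haplotype``, or a floor value if unseen.

    The default floor is the NRC-II-style minimum allele frequency 5/(2N);
    ``one_over_2N`` and a fixed numeric floor are also supported.  A fixed
    floor is mandatory when the table carries no chromosome count.
    """
    rule = parse_floor_rule(floor_rule)
    f = freqs.haplotype_freqs.get(haplotype, 0.0)
    if f > 0:
        return f
    if isinstance(rule, float):
        return rule
    if freqs.chromosome_count <= 0:
        raise FrequencyError(
            f"locus {freqs.locus.name}: haplotype {haplotype} unseen and no chromosome "
            "count recorded; supply an explicit fixed floor"
        )
    numer = 5.0 if rule == "five_over_2N" else 1.0
    return numer / freqs.chromosome_count


# ---------------------------------------------------------------------------
# Capillary-electrophoresis peak observations (shared by the stutter
# statistics, the LR engine's observation extraction, and the simulator).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """One CE peak: an STR allele position with a height in RFU."""

    str_allele: str
    height: float
    dye: str = ""
    size_bp: float | None = None

    def __post_init__(self) -> None:
        str_allele_key(self.str_allele)
        if self.height < 0:
            raise ValueError(f"peak at allele {self.str_allele} has negative height {self.height}")


@dataclass
class PeakProfile:
    """Peaks observed for one (sample, locus, allele-specific primer) reaction."""

    sample_id: str
    locus_name: str
    primer_snp_allele: str
    peaks: list[Peak] = field(default_factory=list)

    def primer_id(self, locus: SNPSTRLocus) -> str:
        return locus.primer_id(self.primer_snp_allele)

    def called_alleles(self, analytical_threshold: float = 50.0) -> set[str]:
        """STR alleles whose peak height reaches the analytical threshold."""
        return {p.str_allele for p in self.peaks if p.height >= analytical_threshold}
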