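"""Informative-genotype probability theory for two-person SNP-STR mixtures.

Allele-specific primers can selectively amplify the minor contributor of an
unbalanced two-person mixture only when the minor contributor carries a SNP
allele absent from the major contributor.  With SNP class frequencies M and
N (M + N = 1), the ordered (major, minor) SNP-genotype pair falls into one
of four exhaustive configuration classes under Hardy–Weinberg equilibrium:

* informative genotype 1 — both contributors homozygous for opposite
  alleles; probability 2 M^2 N^2 (both allele orders counted),
* informative genotype 2 — major homozygous, minor heterozygous;
  probability 2 M^3 N + 2 M N^3,
* informative genotype 3 — both homozygous for the same allele; probability
  M^4 + N^4 (the opposite-allele primer then yields no peaks, which is
  itself evidential),
* uninformative — major heterozygous; probability 2 M^3 N + 4 M^2 N^2 +
  2 M N^3 (no primer can separate the contributors).

The locus informativeness value I = 2 M^2 N^2 + 2 M^3 N + 2 M N^3 is the
probability that selective amplification is possible at all.  Panel-level
projections combine per-locus values assuming independent markers, either
as 1 - prod(1 - I_l) (chance of at least one informative locus) or as exact
binomial tails for a hypothetical panel of markers with a common I.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from scipy.stats import binom

__all__ = [
    "ConfigurationClass",
    "IValues",
    "i_values",
    "classify_configuration",
    "InformativenessProfile",
    "PanelProjection",
    "panel_mean_i",
    "combined_i",
    "expected_informative",
    "panel_projection",
]


class ConfigurationClass(enum.Enum):
    """Configuration of the ordered (major, minor) SNP genotypes at a locus."""

    IG1 = "informative genotype 1"
    IG2 = "informative genotype 2"
    IG3 = "informative genotype 3"
    UNINFORMATIVE = "uninformative genotype"

    def __str__(self) -> str:
        return self.value


def classify_configuration(
    major_snp_genotype: Sequence[str], minor_snp_genotype: Sequence[str]
) -> ConfigurationClass:
    """Classify an ordered (major, minor) pair of SNP genotypes.

    Each genotype is an unordered pair of single-base allele symbols.  The
    function is total on valid inputs: every pair maps to exactly one class.
    """
    maj = tuple(major_snp_genotype)
    mino = tuple(minor_snp_genotype)
    if len(maj) != 2 or len(mino) != 2:
        raise ValueError("SNP genotypes must be pairs of allele symbols")
    major_hom = maj[0] == maj[1]
    minor_hom = mino[0] == mino[1]
    if not major_hom:
        return ConfigurationClass.UNINFORMATIVE
    if not minor_hom:
        return ConfigurationClass.IG2
    return ConfigurationClass.IG3 if maj[0] == mino[0] else ConfigurationClass.IG1


class IValues(NamedTuple):
    i1: float
    i2: float
    i3: float
    i_uninf: float

    @property
    def informative(self) -> float:
        """The locus I value: probability of an informative configuration."""
        return self.i1 + self.i2


def i_values(maf: float) -> IValues:
    """Per-class configuration probabilities from a SNP minor-class frequency.

    With M = 1 - maf and N = maf:
    i1 = 2 M^2 N^2, i2 = 2 M^3 N + 2 M N^3, i3 = M^4 + N^4,
    i_uninf = 2 M^3 N + 4 M^2 N^2 + 2 M N^3; the four sum to (M + N)^4 = 1.

    Values in (0.5, 1] are accepted with a warning — the formulas are
    symmetric in (M, N), so the result is identical to the folded frequency.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"minor allele frequency must lie in [0, 1], got {maf!r}")
    if maf > 0.5:
        warnings.warn(
            f"frequency {maf} exceeds 0.5; treating as the major-class frequency "
            "(class probabilities are symmetric in M and N)",
            stacklevel=2,
        )
    n = maf
    m = 1.0 - maf
    i1 = 2.0 * m * m * n * n
    i2 = 2.0 * m**3 * n + 2.0 * m * n**3
    i3 = m**4 + n**4
    i_uninf = 2.0 * m**3 * n + 4.0 * m * m * n * n + 2.0 * m * n**3
    return IValues(i1, i2, i3, i_uninf)


@dataclass(frozen=True)
class InformativenessProfile:
    """Per-locus configuration-class probabilities derived from the SNP MAF."""

    locus_name: str
    maf: float
    i1: float
    i2: float
    i3: float
    i_uninf: float

    @classmethod
    def from_maf(cls, locus_name: str, maf: float) -> "InformativenessProfile":
        v = i_values(maf)
        return cls(locus_name, maf, v.i1, v.i2, v.i3, v.i_uninf)

    def value(self, cls_: ConfigurationClass) -> float:
        return {
            ConfigurationClass.IG1: self.i1,
            ConfigurationClass.IG2: self.i2,
            ConfigurationClass.IG3: self.i3,
            ConfigurationClass.UNINFORMATIVE: self.i_uninf,
        }[cls_]


def panel_mean_i(
    profiles: Sequence[InformativenessProfile], cls_: ConfigurationClass
) -> float:
    """Arithmetic mean of one class's probability across loci."""
    if not profiles:
        raise ValueError("cannot average an empty panel")
    return sum(p.value(cls_) for p in profiles) / len(profiles)


def combined_i(profiles: Iterable[InformativenessProfile], cls_: ConfigurationClass) -> float:
    """Probability that at least one independent locus shows the class.

    1 - prod(1 - i_l) over the panel; 0 for an empty panel.
    """
    prod = 1.0
    for p in profiles:
        prod *= 1.0 - p.value(cls_)
    return 1.0 - prod


def expected_informative(n_markers: int, i: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n_markers, i), exact tail.

    The tail is the regularized incomplete beta function (no normal
    approximation).  ``k > n_markers`` returns 0; negative ``k`` is an error.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if not 0.0 <= i <= 1.0:
        raise ValueError(f"probability i must lie in [0, 1], got {i!r}")
    if k == 0:
        return 1.0
    if k > n_markers:
        return 0.0
    return float(binom.sf(k - 1, n_markers, i))


@dataclass
class PanelProjection:
    """Cumulative counts of informative markers for a hypothetical panel."""

    n_markers: int
    configuration: ConfigurationClass
    mean_i: float
    cumulative: dict[int, float]  # k -> P(count >= k)


def panel_projection(
    n_markers: int, i: float, cls_: ConfigurationClass, k_max: int | None = None
) -> PanelProjection:
    """Tabulate P(count >= k) for k = 0..k_max at a common per-locus value i."""
    if k_max is None:
        k_max = n_markers
    cumulative = {k: expected_informative(n_markers, i, k) for k in range(k_max + 1)}
    return PanelProjection(n_markers=n_markers, configuration=cls_, mean_i=i, cumulative=cumulative)
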