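"""Shared fixtures: the builtin panel, toy loci, and the worked casework."""

from __future__ import annotations

import pytest

from snpstrmix import (
    Genotype,
    Haplotype,
    LocusFrequencies,
    PeakProfile,
    Peak,
    SNPSTRLocus,
    builtin_panel,
    parse_genotype,
    select_primer,
)

import reference_values as ref


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture
def toy_locus():
    """A 4-haplotype locus with easy hand-checkable frequencies."""
    locus = SNPSTRLocus.from_name("rs0-TOY", ("A", "C"))
    freqs = LocusFrequencies(
        locus=locus,
        haplotype_freqs={
            Haplotype("A", "11"): 0.2,
            Haplotype("A", "14"): 0.1,
            Haplotype("C", "9"): 0.3,
            Haplotype("C", "12"): 0.4,
        },
        chromosome_count=200,
    )
    return locus, freqs


def _casework_locus(name: str) -> SNPSTRLocus:
    pairs = {l.name: l.snp_alleles for l in builtin_panel().loci}
    return SNPSTRLocus.from_name(name, pairs[name])


@pytest.fixture(scope="session")
def casework():
    """The worked casework: genotypes, observations and frequency tables.

    Frequencies are constructed so that every quoted model input is honoured:
    the two IG1 haplotype frequencies, the FGA C22.2 frequency, and each
    locus's SNP minor-class total; the remaining mass within each class is
    spread over filler haplotypes (the closed-form LRs do not depend on it).
    """
    victims: dict[str, Genotype] = {}
    suspects: dict[str, Genotype] = {}
    observations: dict[str, set | None] = {}
    for name, (_, victim, suspect, observed, _) in ref.CASEWORK.items():
        locus = _casework_locus(name)
        victims[name] = parse_genotype(victim, locus)
        suspects[name] = parse_genotype(suspect, locus)
        observations[name] = observed

    freqs: dict[str, LocusFrequencies] = {}
    for name, (minor, maf, *_rest) in ref.PANEL_I_TABLE.items():
        locus = _casework_locus(name)
        major = locus.other_allele(minor)
        quoted = {
            key.split("@")[0]: f
            for key, f in ref.CASEWORK_FREQS.items()
            if key.endswith("@" + name)
        }
        hap_freqs: dict[Haplotype, float] = {}
        class_mass = {minor: maf, major: 1.0 - maf}
        for allele, mass in class_mass.items():
            quoted_here = {
                k[1:]: v for k, v in quoted.items() if k.startswith(allele)
            }
            used = sum(quoted_here.values())
            assert used <= mass + 1e-12
            for str_allele, f in quoted_here.items():
                hap_freqs[Haplotype(allele, str_allele)] = f
            # filler haplotypes at labels far from the casework alleles
            hap_freqs[Haplotype(allele, "30" if allele == major else "31")] = mass - used
        freqs[name] = LocusFrequencies(
            locus=locus, haplotype_freqs=hap_freqs, chromosome_count=226
        )
    return {
        "victims": victims,
        "suspects": suspects,
        "observations": observations,
        "freqs": freqs,
    }


@pytest.fixture(scope="session")
def casework_trace_profiles(casework):
    """Trace peak profiles matching the casework observations (150 RFU calls)."""
    profiles = []
    for name, victim in casework["victims"].items():
        primer = select_primer(victim)
        if primer is None:
            continue
        observed = casework["observations"][name] or set()
        profiles.append(
            PeakProfile(
                sample_id="trace",
                locus_name=name,
                primer_snp_allele=primer.target_snp_allele,
                peaks=[Peak(str_allele=a, height=150.0) for a in sorted(observed)],
            )
        )
    return profiles
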