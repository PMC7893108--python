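"""Primer selection, the unknown-contributor likelihood, and LR combination."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from snpstrmix import (
    CaseLocusResult,
    ConfigurationClass,
    Genotype,
    Haplotype,
    LocusFrequencies,
    Observation,
    PrimerSelection,
    SNPSTRLocus,
    analyze_case,
    combine,
    expected_peaks,
    likelihood_unknown,
    locus_lr,
    parse_genotype,
    select_primer,
)
from snpstrmix.lr_engine import ConfigurationError, EvidenceImpossibleError

import reference_values as ref

TOY = SNPSTRLocus.from_name("rs0-TOY", ("A", "C"))


def hd_enumeration(observation: Observation, freqs: LocusFrequencies) -> float:
    """Brute-force oracle: sum HWE genotype probabilities matching the evidence."""
    haps = list(freqs.haplotype_freqs)
    total = 0.0
    for h1, h2 in itertools.product(haps, repeat=2):
        g = Genotype(freqs.locus, (h1, h2))
        if expected_peaks(g, observation.primer) == observation.detected_str_alleles:
            total += freqs.haplotype_freqs[h1] * freqs.haplotype_freqs[h2]
    return total


def all_observations(primer: PrimerSelection, freqs: LocusFrequencies):
    """Every observation a single unknown can produce with this primer."""
    target_alleles = [
        h.str_allele for h in freqs.haplotype_freqs if h.snp_allele == primer.target_snp_allele
    ]
    sets = [frozenset()]
    sets += [frozenset([a]) for a in target_alleles]
    sets += [
        frozenset(pair) for pair in itertools.combinations(target_alleles, 2)
    ]
    return [Observation(freqs.locus, primer, s) for s in sets]


class TestPrimerSelection:
    def test_victim_snp_homozygous_targets_opposite(self, casework):
        v = casework["victims"]["rs58390469-D2S441"]  # C10/C13
        primer = select_primer(v)
        assert primer is not None and primer.target_snp_allele == "A"

    def test_victim_snp_heterozygous_yields_none(self, casework):
        assert select_primer(casework["victims"]["rs7962284-D12S391"]) is None

    def test_homozygote_single_haplotype(self, casework):
        v = casework["victims"]["rs13413321-TPOX"]  # G8/G8
        assert select_primer(v).target_snp_allele == "T"


class TestExpectedPeaks:
    @pytest.mark.parametrize(
        "suspect, target, expected",
        [
            ("A11/A14", "A", {"11", "14"}),
            ("C22.2/A19", "C", {"22.2"}),
            ("C9/C12", "A", set()),  # no target-class haplotype
            ("A11/A11", "A", {"11"}),
        ],
    )
    def test_target_class_alleles(self, suspect, target, expected):
        g = parse_genotype(suspect, TOY)
        assert expected_peaks(g, PrimerSelection(TOY, target)) == frozenset(expected)


class TestLikelihoodUnknown:
    def test_published_ig1_denominator(self, casework):
        locus = casework["freqs"]["rs58390469-D2S441"]
        primer = PrimerSelection(locus.locus, "A")
        obs = Observation(locus.locus, primer, frozenset({"11", "14"}))
        p = likelihood_unknown(obs, locus)
        assert p == pytest.approx(2 * 0.199 * 0.177)
        assert round(1 / p, 3) == 14.195

    def test_certain_non_detection_when_target_class_absent(self):
        lf = LocusFrequencies(
            locus=TOY, haplotype_freqs={Haplotype("C", "9"): 1.0}, chromosome_count=100
        )
        obs = Observation(TOY, PrimerSelection(TOY, "A"), frozenset())
        assert likelihood_unknown(obs, lf) == pytest.approx(1.0)

    def test_single_allele_closed_form(self, toy_locus):
        _, freqs = toy_locus
        primer = PrimerSelection(TOY, "A")
        obs = Observation(TOY, primer, frozenset({"11"}))
        p, q = 0.2, 0.7  # f(A11), non-target class total
        assert likelihood_unknown(obs, freqs) == pytest.approx(p * p + 2 * p * q)

    def test_matches_enumeration_on_random_tables(self):
        """Closed forms equal brute-force genotype enumeration to 1e-12."""
        rng = np.random.default_rng(99)
        for trial in range(25):
            n_a = int(rng.integers(1, 5))
            n_c = int(rng.integers(1, 5))
            raw = rng.dirichlet(np.ones(n_a + n_c))
            hap_freqs = {}
            for i in range(n_a):
                hap_freqs[Haplotype("A", str(8 + i))] = float(raw[i])
            for j in range(n_c):
                hap_freqs[Haplotype("C", str(8 + j))] = float(raw[n_a + j])
            freqs = LocusFrequencies(TOY, hap_freqs, chromosome_count=1000)
            primer = PrimerSelection(TOY, "A")
            for obs in all_observations(primer, freqs):
                closed = likelihood_unknown(obs, freqs)
                assert closed == pytest.approx(
                    hd_enumeration(obs, freqs), abs=1e-12
                )

    def test_observation_space_normalizes(self, toy_locus):
        """Total probability over all possible observations is exactly 1."""
        _, freqs = toy_locus
        for target in ("A", "C"):
            primer = PrimerSelection(TOY, target)
            total = sum(
                likelihood_unknown(o, freqs) for o in all_observations(primer, freqs)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_floored_frequency_used_for_unseen_allele(self, toy_locus):
        _, freqs = toy_locus
        primer = PrimerSelection(TOY, "A")
        obs = Observation(TOY, primer, frozenset({"99"}))
        f = 5 / 200
        q = 0.7
        assert likelihood_unknown(obs, freqs) == pytest.approx(f * f + 2 * f * q)

    def test_more_than_two_alleles_rejected(self):
        with pytest.raises(ConfigurationError):
            Observation(TOY, PrimerSelection(TOY, "A"), frozenset({"1", "2", "3"}))


class TestLocusLr:
    def test_published_ig1_lr(self, casework):
        name = "rs58390469-D2S441"
        obs = Observation(
            casework["freqs"][name].locus,
            PrimerSelection(casework["freqs"][name].locus, "A"),
            frozenset({"11", "14"}),
        )
        r = locus_lr(
            casework["victims"][name], casework["suspects"][name], obs,
            casework["freqs"][name],
        )
        assert r.configuration is ConfigurationClass.IG1
        assert round(r.lr, 3) == 14.195

    def test_exclusion_when_suspect_mismatches(self, casework):
        name = "rs58390469-D2S441"
        locus = casework["freqs"][name].locus
        obs = Observation(
            locus, PrimerSelection(locus, "A"), frozenset({"11"})
        )  # suspect expects {11, 14}
        r = locus_lr(
            casework["victims"][name], casework["suspects"][name], obs,
            casework["freqs"][name],
        )
        assert r.p_e_hp == 0.0 and r.lr == 0.0

    def test_ig3_no_peaks_closed_form(self, toy_locus):
        _, freqs = toy_locus
        victim = parse_genotype("C9/C12", TOY)
        suspect = parse_genotype("C9/C9", TOY)
        obs = Observation(TOY, PrimerSelection(TOY, "A"), frozenset())
        r = locus_lr(victim, suspect, obs, freqs)
        target_total = 0.3  # f(A11) + f(A14)
        assert r.configuration is ConfigurationClass.IG3
        assert r.lr == pytest.approx(1 / (1 - target_total) ** 2)
        assert r.lr == pytest.approx(1 / hd_enumeration(obs, freqs))

    def test_ig1_heterozygous_suspect_identity(self, toy_locus):
        """IG1 with SNP-hom/STR-het suspect gives LR = 1 / (2 f(a) f(b))."""
        _, freqs = toy_locus
        victim = parse_genotype("C9/C12", TOY)
        suspect = parse_genotype("A11/A14", TOY)
        obs = Observation(TOY, PrimerSelection(TOY, "A"), frozenset({"11", "14"}))
        r = locus_lr(victim, suspect, obs, freqs)
        assert r.lr == pytest.approx(1 / (2 * 0.2 * 0.1))

    def test_uninformative_locus_has_no_lr(self, toy_locus):
        _, freqs = toy_locus
        victim = parse_genotype("A11/C9", TOY)
        suspect = parse_genotype("A11/A14", TOY)
        r = locus_lr(victim, suspect, None, freqs)
        assert r.configuration is ConfigurationClass.UNINFORMATIVE
        assert r.lr is None and r.p_e_hp is None

    def test_wrong_primer_is_configuration_error(self, toy_locus):
        _, freqs = toy_locus
        victim = parse_genotype("C9/C12", TOY)  # calls for the A-primer
        suspect = parse_genotype("A11/A14", TOY)
        obs = Observation(TOY, PrimerSelection(TOY, "C"), frozenset({"9"}))
        with pytest.raises(ConfigurationError):
            locus_lr(victim, suspect, obs, freqs)

    def test_impossible_evidence_raises_model_error(self):
        lf = LocusFrequencies(
            locus=TOY, haplotype_freqs={Haplotype("C", "9"): 1.0}, chromosome_count=0
        )
        victim = parse_genotype("C9/C9", TOY)
        suspect = parse_genotype("C9/C9", TOY)
        obs = Observation(TOY, PrimerSelection(TOY, "A"), frozenset({"11"}))
        with pytest.raises(EvidenceImpossibleError):
            locus_lr(victim, suspect, obs, lf, floor_rule=0.0)


def turing_expectation(freqs: LocusFrequencies, victim_text: str, suspect_text: str):
    victim = parse_genotype(victim_text, freqs.locus)
    suspect = parse_genotype(suspect_text, freqs.locus)
    primer = select_primer(victim)
    total = 0.0
    for obs in all_observations(primer, freqs):
        p_hd = likelihood_unknown(obs, freqs)
        r = locus_lr(victim, suspect, obs, freqs)
        total += p_hd * r.lr
    return total


class TestTuringIdentity:
    def test_mean_lr_under_hd_is_one_by_enumeration(self, toy_locus):
        _, freqs = toy_locus
        for suspect in ("A11/A14", "A11/C9", "C9/C12", "A11/A11"):
            assert turing_expectation(freqs, "C9/C12", suspect) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_mean_lr_under_hd_monte_carlo(self, toy_locus):
        """Over >=10,000 Hd-true cases the empirical mean LR is 1 within 3 SE."""
        _, freqs = toy_locus
        victim = parse_genotype("C9/C12", TOY)
        suspect = parse_genotype("A11/C9", TOY)
        primer = select_primer(victim)
        haps = list(freqs.haplotype_freqs)
        probs = np.array([freqs.haplotype_freqs[h] for h in haps])
        rng = np.random.default_rng(2024)
        n = 20_000
        draws = rng.choice(len(haps), size=(n, 2), p=probs)
        lrs = np.empty(n)
        for i, (a, b) in enumerate(draws):
            unknown = Genotype(TOY, (haps[a], haps[b]))
            obs = Observation(TOY, primer, expected_peaks(unknown, primer))
            lrs[i] = locus_lr(victim, suspect, obs, freqs).lr
        se = lrs.std(ddof=1) / math.sqrt(n)
        assert abs(lrs.mean() - 1.0) < 3 * se
        # Markov bound on large LRs under Hd
        for x in (10.0, 100.0):
            frac = (lrs >= x).mean()
            assert frac <= 1 / x + 3 * math.sqrt((1 / x) * (1 - 1 / x) / n)


class TestCombine:
    def _results(self, pairs):
        return [
            CaseLocusResult(
                locus_name=f"L{i}",
                configuration=cls_,
                observation=None,
                p_e_hp=None if lr is None else (0.0 if lr == 0 else 1.0),
                p_e_hd=None if lr in (None, 0.0) else 1.0 / lr,
                lr=lr,
            )
            for i, (cls_, lr) in enumerate(pairs)
        ]

    def test_published_casework_aggregation(self):
        results = self._results(
            [
                (ConfigurationClass[cls_], lr)
                for cls_, _, _, _, lr in ref.CASEWORK.values()
                if lr is not None
            ]
            + [(ConfigurationClass.UNINFORMATIVE, None)] * 3
        )
        report = combine(results)
        ig2_n, ig2_avg, ig2_comb = ref.CASE_SUMMARY["IG2"]
        assert report.class_counts[ConfigurationClass.IG2] == ig2_n
        assert report.class_average_lr[ConfigurationClass.IG2] == pytest.approx(
            ig2_avg, abs=5e-4
        )
        assert report.class_combined_lr[ConfigurationClass.IG2] == pytest.approx(
            ig2_comb, rel=5e-3
        )
        ig3_n, ig3_avg, ig3_comb = ref.CASE_SUMMARY["IG3"]
        assert report.class_average_lr[ConfigurationClass.IG3] == pytest.approx(
            ig3_avg, abs=5e-4
        )
        assert report.class_combined_lr[ConfigurationClass.IG3] == pytest.approx(
            ig3_comb, rel=5e-3
        )
        assert report.combined_lr == pytest.approx(ref.CASE_COMBINED_LR, rel=0.01)
        assert report.n_informative == 15

    def test_single_and_empty(self):
        single = self._results([(ConfigurationClass.IG1, 5.0)])
        assert combine(single).combined_lr == pytest.approx(5.0)
        with pytest.raises(ValueError):
            combine(self._results([(ConfigurationClass.UNINFORMATIVE, None)]))

    def test_order_invariance(self):
        pairs = [(ConfigurationClass.IG2, x) for x in (2.0, 30.0, 0.5, 7.1)]
        fwd = combine(self._results(pairs)).combined_lr
        rev = combine(self._results(pairs[::-1])).combined_lr
        assert fwd == pytest.approx(rev)

    def test_log10_accumulation_handles_extremes(self):
        pairs = [(ConfigurationClass.IG2, 1e200), (ConfigurationClass.IG2, 1e200)]
        report = combine(self._results(pairs))
        assert report.log10_combined_lr == pytest.approx(400.0)
        pairs.append((ConfigurationClass.IG2, 0.0))
        report = combine(self._results(pairs))
        assert report.combined_lr == 0.0
        assert report.log10_combined_lr == -math.inf


class TestAnalyzeCase:
    def test_full_casework_class_partition(self, casework, casework_trace_profiles):
        report = analyze_case(
            casework["victims"], casework["suspects"], casework_trace_profiles,
            casework["freqs"],
        )
        counts = {c.name: n for c, n in report.class_counts.items()}
        assert counts == {"IG1": 1, "IG2": 8, "IG3": 6, "UNINFORMATIVE": 3}
        assert report.n_informative == 15
        assert report.combined_lr > 1.0

    def test_hp_true_simulated_case_never_excludes(self, panel):
        from snpstrmix import MixtureScenario, simulate_case

        scenario = MixtureScenario(
            ratio=100.0, sensitivity=panel.sensitivity, stutter_model=panel.stutter
        )
        for seed in range(3):
            case = simulate_case(panel, scenario, truth="hp", seed=seed)
            report = analyze_case(
                case.victim, case.suspect, case.profiles, panel.frequencies
            )
            assert all(r.lr is None or r.lr >= 1.0 for r in report.results)

    def test_extra_alleles_flagged_and_excluded(self, toy_locus, recwarn):
        from snpstrmix import Peak, PeakProfile

        _, freqs = toy_locus
        victim = {"rs0-TOY": parse_genotype("C9/C12", TOY)}
        suspect = {"rs0-TOY": parse_genotype("A11/A14", TOY)}
        trace = [
            PeakProfile(
                sample_id="t", locus_name="rs0-TOY", primer_snp_allele="A",
                peaks=[Peak(a, 200.0) for a in ("10", "11", "14")],
            )
        ]
        with pytest.raises(ValueError):
            # the only locus is excluded, so nothing remains to combine
            analyze_case(victim, suspect, trace, {"rs0-TOY": freqs})
        assert any("extra" in str(w.message) for w in recwarn.list)

    def test_trace_with_victim_class_primer_rejected(self, toy_locus):
        from snpstrmix import Peak, PeakProfile

        _, freqs = toy_locus
        victim = {"rs0-TOY": parse_genotype("C9/C12", TOY)}
        suspect = {"rs0-TOY": parse_genotype("A11/A14", TOY)}
        trace = [
            PeakProfile(
                sample_id="t", locus_name="rs0-TOY", primer_snp_allele="C",
                peaks=[Peak("9", 500.0)],
            )
        ]
        with pytest.raises(ConfigurationError):
            analyze_case(victim, suspect, trace, {"rs0-TOY": freqs})

    def test_sub_threshold_peaks_not_called(self, toy_locus):
        from snpstrmix import Peak, PeakProfile

        _, freqs = toy_locus
        victim = {"rs0-TOY": parse_genotype("C9/C12", TOY)}
        suspect = {"rs0-TOY": parse_genotype("C9/C9", TOY)}  # expects no A peaks
        trace = [
            PeakProfile(
                sample_id="t", locus_name="rs0-TOY", primer_snp_allele="A",
                peaks=[Peak("11", 49.0)],  # just below the 50 RFU threshold
            )
        ]
        report = analyze_case(victim, suspect, trace, {"rs0-TOY": freqs})
        assert report.results[0].observation.detected_str_alleles == frozenset()
        assert report.results[0].lr == pytest.approx(1 / 0.7**2)
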