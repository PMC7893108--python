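"""Forensic population-genetics summary statistics for SNP-STR panels.

Match probability / power of discrimination (Powerstats convention: MP is
the sum of squared *observed* genotype proportions, PD = 1 - MP), their
multi-locus cumulative forms, observed and unbiased expected heterozygosity,
a Monte-Carlo exact test of Hardy-Weinberg equilibrium for multi-allelic
loci, and stutter-ratio statistics with the mean + 3 SD filter threshold
used to screen CE profiles before mixture interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplotype_model import (
    Genotype,
    Haplotype,
    PeakProfile,
    SnpStrError,
    str_allele_key,
)

__all__ = [
    "ForensicParams",
    "match_probability",
    "cumulative_match_probability",
    "heterozygosities",
    "hwe_exact_test",
    "StutterStats",
    "stutter_stats",
    "compute_forensic_params",
]


@dataclass(frozen=True)
class ForensicParams:
    """Per-locus forensic summary: MP, PD, heterozygosities, HWE p-value."""

    locus_name: str
    mp: float
    pd: float
    h_obs: float
    h_exp: float
    hwe_p: float


def match_probability(genotype_counts: Mapping[Genotype, int]) -> tuple[float, float]:
    """Match probability and power of discrimination from genotype counts.

    MP = sum over genotypes of (count / total)^2 — the probability that two
    random individuals from the sample share a genotype; PD = 1 - MP.
    """
    if not genotype_counts:
        raise ValueError("match_probability requires at least one genotype")
    total = sum(genotype_counts.values())
    if total < 1:
        raise ValueError("match_probability requires a positive total count")
    mp = sum((c / total) ** 2 for c in genotype_counts.values())
    return mp, 1.0 - mp


def cumulative_match_probability(mps: Sequence[float]) -> tuple[float, float]:
    """Cumulative MP (product over loci) and cumulative PD (its complement)."""
    if not mps:
        raise ValueError("cumulative_match_probability requires at least one locus")
    cmp_ = float(np.prod(np.asarray(mps, dtype=float)))
    return cmp_, 1.0 - cmp_


def heterozygosities(genotypes: Sequence[Genotype]) -> tuple[float, float]:
    """Observed and Nei's unbiased expected haplotype heterozygosity.

    h_obs is the fraction of individuals whose two haplotypes differ.
    h_exp = (2n / (2n - 1)) * (1 - sum p_h^2) over the estimated haplotype
    frequencies; requires at least two typed individuals.
    """
    n = len(genotypes)
    if n < 2:
        raise ValueError("heterozygosities require at least 2 typed individuals")
    h_obs = sum(1 for g in genotypes if g.is_heterozygous) / n
    counts: dict[Haplotype, int] = {}
    for g in genotypes:
        for h in g.haplotypes:
            counts[h] = counts.get(h, 0) + 1
    two_n = 2 * n
    sum_p2 = sum((c / two_n) ** 2 for c in counts.values())
    h_exp = (two_n / (two_n - 1)) * (1.0 - sum_p2)
    return h_obs, h_exp


def _table_statistic(pair_counts: np.ndarray, het_mask: np.ndarray) -> float:
    """log of the pairing-conditional table weight, up to an additive constant.

    For a genotype table with heterozygote count h and genotype counts n_g,
    the conditional probability given allele counts is proportional to
    2^h / prod(n_g!); we compare tables through h*log2 - sum(lgamma(n_g+1)).
    """
    lg = np.vectorize(math.lgamma)(pair_counts + 1.0)
    h = int(pair_counts[het_mask].sum())
    return h * math.log(2.0) - float(lg.sum())


def hwe_exact_test(
    genotypes: Sequence[Genotype], mc_reps: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    The 2n observed haplotypes are repeatedly shuffled into n random diploid
    pairings; the p-value is the proportion of shuffles whose conditional
    table probability is <= that of the observed table (ties counted as <=).
    Monomorphic loci return p = 1 by convention.  Deterministic given
    (data, mc_reps, seed).
    """
    if mc_reps < 1:
        raise ValueError("mc_reps must be >= 1")
    if not genotypes:
        raise ValueError("hwe_exact_test requires at least one genotype")
    alleles: list[Haplotype] = sorted(
        {h for g in genotypes for h in g.haplotypes}, key=lambda h: h.sort_key
    )
    if len(alleles) < 2:
        return 1.0
    index = {h: i for i, h in enumerate(alleles)}
    k = len(alleles)
    tokens = np.array(
        [index[h] for g in genotypes for h in g.haplotypes], dtype=np.int64
    )
    n = len(genotypes)

    def tabulate(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        codes = lo * k + hi
        return np.bincount(codes, minlength=k * k).astype(float)

    obs_lo = np.minimum(tokens[::2], tokens[1::2])
    obs_hi = np.maximum(tokens[::2], tokens[1::2])
    het_mask = (np.arange(k * k) // k) != (np.arange(k * k) % k)
    t_obs = _table_statistic(tabulate(obs_lo, obs_hi), het_mask)

    rng = np.random.default_rng(seed)
    lgamma_table = np.array([math.lgamma(i + 1.0) for i in range(n + 1)])
    log2 = math.log(2.0)
    hits = 0
    done = 0
    chunk = max(1, min(512, mc_reps))
    while done < mc_reps:
        b = min(chunk, mc_reps - done)
        # batched random permutations of the token vector
        order = np.argsort(rng.random((b, 2 * n)), axis=1)
        perm = tokens[order]
        a1 = perm[:, ::2]
        a2 = perm[:, 1::2]
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        codes = lo * k + hi + (np.arange(b)[:, None] * k * k)
        counts = np.bincount(codes.ravel(), minlength=b * k * k).reshape(b, k * k)
        t = (lo != hi).sum(axis=1) * log2 - lgamma_table[counts].sum(axis=1)
        hits += int((t <= t_obs + 1e-9).sum())
        done += b
    return hits / mc_reps


@dataclass(frozen=True)
class StutterStats:
    """Stutter-ratio statistics for one allele-specific primer.

    ``filter_threshold`` is mean + 3 SD, the recommended per-primer stutter
    filter for mixture analysis.  With a single qualifying observation the
    SD is undefined and reported as 0 with ``sd_defined`` False.
    """

    primer_id: str
    mean_ratio: float
    sd_ratio: float
    n_observations: int
    sd_defined: bool

    @property
    def filter_threshold(self) -> float:
        return self.mean_ratio + 3.0 * self.sd_ratio


def stutter_stats(
    profiles: Iterable[PeakProfile],
    stutter_height_min: float = 20.0,
    analytical_threshold: float = 50.0,
) -> dict[str, StutterStats]:
    """Per-primer stutter ratios from single-source CE profiles.

    Parent alleles are the called peaks (height >= analytical threshold).
    Every peak exactly one repeat unit above or below a parent, with height
    >= ``stutter_height_min`` (default 20 RFU) and no taller than half the
    parent (an artifact-scale guard against counting a genuine adjacent
    allele as stutter), contributes one ratio = stutter height / parent
    height.  Peaks two or more repeats away never qualify.  Primers with
    zero qualifying observations are absent from the result (never reported
    as zero).
    """
    ratios: dict[str, list[float]] = {}
    for profile in profiles:
        snp_id, _, str_name = profile.locus_name.partition("-")
        if not str_name:
            raise SnpStrError(
                f"peak profile locus {profile.locus_name!r} is not of the form "
                "<snp_id>-<str_name>"
            )
        primer = f"{snp_id}{profile.primer_snp_allele}-{str_name}"
        called = {
            str_allele_key(p.str_allele): p for p in profile.peaks
            if p.height >= analytical_threshold
        }
        for p in profile.peaks:
            if p.height < stutter_height_min:
                continue
            key = str_allele_key(p.str_allele)
            # back-stutter sits one repeat below its parent (parent at key+10);
            # forward stutter one repeat above (parent at key-10)
            for delta in (+10, -10):
                parent = called.get(key + delta)
                if parent is None or parent is p or p.height > 0.5 * parent.height:
                    continue
                ratios.setdefault(primer, []).append(p.height / parent.height)
                break  # attribute each candidate to a single parent
    out: dict[str, StutterStats] = {}
    for primer, vals in sorted(ratios.items()):
        arr = np.asarray(vals, dtype=float)
        mean = float(arr.mean())
        if arr.size > 1:
            sd = float(arr.std(ddof=1))
            sd_defined = True
        else:
            sd = 0.0
            sd_defined = False
        out[primer] = StutterStats(
            primer_id=primer,
            mean_ratio=mean,
            sd_ratio=sd,
            n_observations=int(arr.size),
            sd_defined=sd_defined,
        )
    return out


def compute_forensic_params(
    genotypes_by_locus: Mapping[str, Sequence[Genotype]],
    mc_reps: int = 100_000,
    seed: int = 0,
) -> list[ForensicParams]:
    """MP/PD, heterozygosities, and HWE p-value for each locus of a survey."""
    out = []
    for i, (locus_name, genotypes) in enumerate(genotypes_by_locus.items()):
        counts: dict[Genotype, int] = {}
        for g in genotypes:
            counts[g] = counts.get(g, 0) + 1
        mp, pd = match_probability(counts)
        h_obs, h_exp = heterozygosities(genotypes)
        # one independent stream per locus, reproducible for fixed input order
        p = hwe_exact_test(genotypes, mc_reps=mc_reps, seed=seed + i)
        out.append(ForensicParams(locus_name, mp, pd, h_obs, h_exp, p))
    return out
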