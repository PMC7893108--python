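"""Published reference values for the 18-locus SNP-STR panel.

Survey constants (SNP minor-class frequencies, per-class informativeness
probabilities rounded to 3 d.p., per-locus match probabilities) and the
worked two-person casework example (reference genotypes, trace observations
and reported per-locus likelihood ratios) used as frozen expectations in the
test suite.
"""

# locus -> (minor SNP allele, minor class frequency,
#           I_ig1, I_ig2, I_ig3 as published at 3 d.p.)
PANEL_I_TABLE = {
    "rs11642858-D16S539": ("C", 0.447, 0.122, 0.25, 0.133),
    "rs58390469-D2S441": ("C", 0.478, 0.125, 0.25, 0.126),
    "rs2325399-D6S1043": ("G", 0.3982, 0.115, 0.25, 0.156),
    "rs2070018-FGA": ("C", 0.097, 0.015, 0.144, 0.665),
    "rs25768-D5S818": ("A", 0.062, 0.007, 0.103, 0.774),
    "rs9531308-D13S317": ("C", 0.469, 0.124, 0.25, 0.128),
    "rs8031604-Penta E": ("T", 0.058, 0.006, 0.097, 0.787),
    "rs4847015-D1S1656": ("T", 0.128, 0.025, 0.173, 0.578),
    "rs7962284-D12S391": ("C", 0.305, 0.09, 0.244, 0.242),
    "rs7275705-Penta D": ("G", 0.2552, 0.072, 0.236, 0.312),
    "rs7786079-D7S820": ("C", 0.022, 0.001, 0.041, 0.915),
    "rs57346531-D8S1179": ("G", 0.3142, 0.093, 0.245, 0.231),
    "rs2246512-D10S1248": ("G", 0.3142, 0.093, 0.245, 0.231),
    "rs17077990-D3S1358": ("G", 0.19, 0.047, 0.213, 0.432),
    "rs17651965-CSF1PO": ("G", 0.407, 0.117, 0.25, 0.151),
    "rs6736691-D2S1338": ("A", 0.093, 0.014, 0.14, 0.677),
    "rs13413321-TPOX": ("G", 0.487, 0.125, 0.25, 0.126),
    "rs9362476-SE33": ("T", 0.385, 0.112, 0.249, 0.165),
}

# published panel averages and combined (at-least-one) values
PANEL_AVERAGE = (0.0724, 0.202, 0.379)
PANEL_COMBINED = (0.747, 0.984, 0.999989)

# 40-marker cumulative binomial projection: k -> published P(count >= k)
# at the per-class average probabilities above
PROJECTION_40 = {
    "IG1": {1: 0.951, 2: 0.796, 3: 0.561, 4: 0.328, 5: 0.161, 6: 0.066,
            7: 0.023, 8: 0.007, 9: 0.002, 10: 4.437e-04, 11: 9.183e-05},
    "IG2": {1: 1.0, 2: 0.999, 3: 0.993, 4: 0.973, 5: 0.928, 6: 0.846,
            7: 0.725, 8: 0.575, 9: 0.419, 10: 0.279, 11: 0.169},
    "IG3": {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0, 6: 1.0,
            7: 0.999, 8: 0.995, 9: 0.988, 10: 0.971, 11: 0.938},
}
PROJECTION_TEXT = {("IG1", 1): 0.9505, ("IG2", 5): 0.9283, ("IG3", 10): 0.9706}

# per-locus match probabilities of the 18 SNP-STR markers (MP, PD)
SNPSTR_MP_PD = {
    "rs11642858-D16S539": (0.061, 0.939),
    "rs58390469-D2S441": (0.044, 0.956),
    "rs2325399-D6S1043": (0.035, 0.965),
    "rs2070018-FGA": (0.039, 0.961),
    "rs25768-D5S818": (0.06, 0.94),
    "rs9531308-D13S317": (0.058, 0.942),
    "rs8031604-Penta E": (0.019, 0.981),
    "rs4847015-D1S1656": (0.064, 0.936),
    "rs7962284-D12S391": (0.047, 0.953),
    "rs7275705-Penta D": (0.044, 0.956),
    "rs7786079-D7S820": (0.088, 0.912),
    "rs57346531-D8S1179": (0.042, 0.958),
    "rs2246512-D10S1248": (0.042, 0.958),
    "rs17077990-D3S1358": (0.071, 0.929),
    "rs17651965-CSF1PO": (0.061, 0.939),
    "rs6736691-D2S1338": (0.045, 0.955),
    "rs13413321-TPOX": (0.185, 0.815),
    "rs9362476-SE33": (0.016, 0.984),
}
CMP_18_SNPSTR = 2.87e-24  # product of the 18 MP values, 3 s.f.

# worked casework example: locus -> (class, victim, suspect, observed trace
# STR alleles with the victim-opposite primer, reported LR).  None for the
# observation means the locus was uninformative (victim SNP-heterozygous).
CASEWORK = {
    "rs58390469-D2S441": ("IG1", "C10-C13", "A11-A14", {"11", "14"}, 14.195),
    "rs11642858-D16S539": ("IG2", "A13-A13", "A11-C9", {"9"}, 2.814),
    "rs2070018-FGA": ("IG2", "T22-T23", "C22.2-T19", {"22.2"}, 30.525),
    "rs9531308-D13S317": ("IG2", "C12-C12", "A8-C10", {"8"}, 2.451),
    "rs7275705-Penta D": ("IG2", "C9-C9", "G12-C8", {"12"}, 7.535),
    "rs57346531-D8S1179": ("IG2", "A10-A10", "G15-A11", {"15"}, 3.747),
    "rs17077990-D3S1358": ("IG2", "C15-C17", "C15-G16", {"16"}, 6.995),
    "rs17651965-CSF1PO": ("IG2", "G12-G13", "G11-C10", {"10"}, 4.470),
    "rs13413321-TPOX": ("IG2", "G8-G8", "G8-T11", {"11"}, 2.563),
    "rs2325399-D6S1043": ("IG3", "C10-C13", "C11-C14", set(), 2.769),
    "rs25768-D5S818": ("IG3", "G10-G11", "G10-G11", set(), 1.139),
    "rs8031604-Penta E": ("IG3", "G11-G16", "G13-G16", set(), 1.129),
    "rs4847015-D1S1656": ("IG3", "C11-C16", "C11-C15", set(), 1.318),
    "rs7786079-D7S820": ("IG3", "A11-A11", "A8-A11", set(), 1.048),
    "rs2246512-D10S1248": ("IG3", "A14-A15", "A13-A15", set(), 2.131),
    "rs7962284-D12S391": ("UNINFORMATIVE", "T19-C21", "T20-T20", None, None),
    "rs6736691-D2S1338": ("UNINFORMATIVE", "A17-C23", "C19-C19", None, None),
    "rs9362476-SE33": ("UNINFORMATIVE", "T17-C25.2", "T17-C24.2", None, None),
}

# haplotype frequencies quoted for the IG1 and FGA casework loci
CASEWORK_FREQS = {"A11@rs58390469-D2S441": 0.199, "A14@rs58390469-D2S441": 0.177,
                  "C22.2@rs2070018-FGA": 0.018}

# published case-level aggregation: class -> (n, average LR, combined LR)
CASE_SUMMARY = {
    "IG1": (1, 14.195, 14.195),
    "IG2": (8, 7.638, 4.76e5),
    "IG3": (6, 1.589, 10.481),
}
CASE_COMBINED_LR = 7.14e7
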