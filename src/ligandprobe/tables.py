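"""Published per-atom statistics for the 6UG0 nitrogenase evaluation.

These are the printed per-atom values from the critical re-evaluation of
PDB entry 6UG0 (Mo nitrogenase under N2 turnover): sphere-integrated
2mFo-DFc and anomalous densities for the ten sulfur atoms of each FeMo
cluster (radius 1.05 A), and the per-region RSZD scores of the
quantum-refined models.  They serve as inputs for the population
statistics and report aggregation in this package; the deposited maps
themselves are not required to recompute any of the derived columns.

Sulfur order follows the published rows: Cys thiolate first, then the
three mu2 belt sites, then the six mu3 sulfides.
"""

SULFUR_SITES = ["Cys", "S2B", "S3A", "S5A", "S1A", "S2A", "S4A", "S1B", "S3B", "S4B"]

#: sphere-integrated 2mFo-DFc density (e), radius 1.05 A, per chain
INTEGRATED_DENSITY = {
    "A": [19.2, 21.6, 21.7, 20.4, 17.8, 20.9, 25.3, 22.3, 22.4, 23.6],
    "C": [21.7, 23.6, 25.4, 25.2, 29.0, 27.1, 27.2, 30.5, 26.6, 24.3],
}

#: all-structure sulfur reference population for the density table (mean, sd)
INTEGRATED_DENSITY_ALL_REF = (18.5, 5.1)

#: sphere-integrated anomalous density (e), 7100 eV maps, radius 1.05 A
INTEGRATED_ANOMALOUS = {
    "A": [12.0, 6.0, 9.0, 8.4, 8.4, 11.2, 9.4, 7.3, 8.1, 10.0],
    "C": [14.0, 11.9, 8.6, 8.8, 9.7, 13.0, 11.5, 9.7, 8.2, 8.8],
}

#: all-structure sulfur reference population for the anomalous table
INTEGRATED_ANOMALOUS_ALL_REF = (9.2, 2.5)

#: chain-A quantum-refinement RSZD scores per region
#: regions: Arg96, Cys275, Arg359, His442, HCA601, FeMo, 2B
RSZD_CHAIN_A_REGIONS = ["Arg96", "Cys275", "Arg359", "His442", "HCA601", "FeMo", "2B"]
RSZD_CHAIN_A = {
    "S2- q=-3": [0.2, 0.3, 0.7, 1.0, 6.6, 10.9, 2.1],
    "N2 q=-1": [0.2, 0.4, 0.6, 1.0, 6.9, 11.2, 2.7],
    "N2 q=-3": [0.2, 0.3, 0.6, 1.1, 6.6, 11.4, 3.5],
}

#: chain-C quantum-refinement RSZD scores per region
RSZD_CHAIN_C_REGIONS = ["Arg96", "Cys275", "Arg359", "His442", "HCA", "FeMo", "3A", "5A"]
RSZD_CHAIN_C = {
    "S2-/S2- q=-3": [0.3, 0.1, 1.5, 0.7, 1.6, 7.7, 3.0, 1.4],
    "S2-/N2 q=-1": [0.3, 0.1, 1.3, 0.6, 1.7, 8.5, 2.9, 3.3],
    "S2-/N2 q=-3": [0.4, 0.1, 1.4, 0.7, 1.6, 7.2, 3.1, 3.7],
    "N2/S2- q=-1": [0.4, 0.1, 1.6, 0.5, 1.8, 8.6, 6.3, 1.2],
    "N2/S2- q=-3": [0.3, 0.1, 1.4, 0.5, 1.8, 8.6, 5.1, 1.3],
    "N2/N2 q=+1": [0.5, 0.1, 1.6, 0.7, 1.8, 9.3, 6.1, 3.2],
}
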