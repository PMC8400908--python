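"""Published summary statistics of the motivating warfarin cohort.

The motivating study followed 142 warfarin-treated patients with mechanical
heart valves maintaining therapeutic INRs (2-3), of whom 21 experienced
professionally verified bleeding complications.  Sixteen SNPs in the
renin-angiotensin system plus *VKORC1*/*CYP2C9* were genotyped, three *ACE*
SNPs (rs1800764, rs4341, rs4353) were phased into haplotypes, and bleeding
risk was modelled by multivariable logistic regression.

This module records the study's *printed* summary numbers — per-SNP grouped
genotype counts by outcome, covariate counts, *ACE* haplotype frequencies,
adjusted odds ratios and the weighted-risk-score strata — as package data.
They serve two purposes: (i) desk-level verification that the statistical
machinery reproduces every quantity computable from printed counts, and
(ii) defaults for the synthetic cohort generator.

:func:`reconstruct_demo_cohort` rebuilds a subject-level cohort whose
per-column margins equal the printed counts exactly (the joint distribution
across columns is not recoverable from the publication and is filled in
deterministically; see the function docstring).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import GenotypeMatrix, PhenotypeTable, SnpDef

__all__ = [
    "SNP_DEFS",
    "ACE_LOCI",
    "ACE_HAPLOTYPES",
    "GENOTYPE_GROUP_COUNTS",
    "COVARIATE_GROUP_COUNTS",
    "COVARIATE_PREVALENCES",
    "ADJUSTED_OR",
    "H2_SEQUENCE",
    "N_CASES",
    "N_CONTROLS",
    "N_TOTAL",
    "OVERALL_INCIDENCE",
    "WRS_STRATA_COUNTS",
    "WRS_PERCENTILE_CUTS",
    "reconstruct_demo_cohort",
    "demo_wrs_fixture",
]

N_CASES = 21
N_CONTROLS = 121
N_TOTAL = N_CASES + N_CONTROLS
#: Cohort bleeding incidence at therapeutic INR, 21/142.
OVERALL_INCIDENCE = N_CASES / N_TOTAL

#: The 16 genotyped SNPs.  The minor allele is the one whose declared
#: frequency (MAF column of the published genotype table) is below 0.5;
#: the grouping model reproduces the published "grouped genotypes" split.
SNP_DEFS = (
    SnpDef("rs9934438", "VKORC1", "T", "C", 0.113, "carrier_dominant"),
    SnpDef("rs1057910", "CYP2C9", "A", "C", 0.043, "het_vs_ref"),
    SnpDef("rs7079", "AGT", "G", "T", 0.128, "carrier_dominant"),
    SnpDef("rs699", "AGT", "G", "A", 0.180, "carrier_dominant"),
    SnpDef("rs11122576", "AGT", "T", "C", 0.401, "variant_recessive"),
    SnpDef("rs5050", "AGT", "T", "G", 0.165, "carrier_dominant"),
    SnpDef("rs2368564", "REN", "C", "T", 0.225, "carrier_dominant"),
    SnpDef("rs12750834", "REN", "G", "A", 0.373, "carrier_dominant"),
    SnpDef("rs1800764", "ACE", "T", "C", 0.465, "carrier_dominant"),
    SnpDef("rs4341", "ACE", "C", "G", 0.437, "carrier_dominant"),
    SnpDef("rs4353", "ACE", "G", "A", 0.486, "carrier_dominant"),
    SnpDef("rs275651", "AGTR1", "T", "A", 0.094, "carrier_dominant"),
    SnpDef("rs2640543", "AGTR1", "G", "A", 0.190, "carrier_dominant"),
    SnpDef("rs5182", "AGTR1", "T", "C", 0.254, "variant_recessive"),
    SnpDef("rs5186", "AGTR1", "A", "C", 0.060, "het_vs_ref"),
    SnpDef("rs1403543", "AGTR2", "G", "A", 0.310, "carrier_dominant"),
)

SNP_BY_ID = {s.snp_id: s for s in SNP_DEFS}

#: The *ACE* haplotype block, in genomic order.
ACE_LOCI = ("rs1800764", "rs4341", "rs4353")

#: Haplotypes of the *ACE* block detected above 1% frequency in the cohort
#: (sequence over rs1800764-rs4341-rs4353, population frequency).  H2 (TCG)
#: carries the variant allele at every locus and is protective as a
#: homozygous diplotype.
ACE_HAPLOTYPES = (
    ("CGA", 0.418),  # H1
    ("TCG", 0.470),  # H2
    ("TCA", 0.047),  # H3
    ("CCG", 0.041),  # H4
    ("TGA", 0.014),  # H5
)
H2_SEQUENCE = "TCG"

#: Grouped-genotype counts by bleeding outcome:
#: snp_id -> (exposed cases, exposed controls, unexposed cases,
#:            unexposed controls, missing cases, missing controls),
#: where "exposed" follows the SNP's grouping model in SNP_DEFS.
GENOTYPE_GROUP_COUNTS = {
    "rs9934438": (3, 27, 18, 94, 0, 0),
    "rs1057910": (3, 9, 18, 111, 0, 1),
    "rs7079": (2, 33, 19, 87, 0, 1),
    "rs699": (5, 42, 16, 79, 0, 0),
    "rs11122576": (19, 99, 2, 22, 0, 0),
    "rs5050": (13, 32, 8, 89, 0, 0),
    "rs2368564": (7, 50, 14, 71, 0, 0),
    "rs12750834": (14, 69, 7, 52, 0, 0),
    "rs1800764": (18, 78, 3, 43, 0, 0),
    "rs4341": (18, 76, 3, 45, 0, 0),
    "rs4353": (20, 84, 1, 37, 0, 0),
    "rs275651": (3, 22, 17, 97, 1, 2),
    "rs2640543": (11, 36, 10, 85, 0, 0),
    "rs5182": (18, 115, 3, 6, 0, 0),
    "rs5186": (3, 14, 18, 107, 0, 0),
    "rs1403543": (18, 101, 3, 20, 0, 0),
}

#: Binary covariate counts by outcome:
#: name -> (cases with, controls with, missing cases, missing controls).
COVARIATE_GROUP_COUNTS = {
    "sex_male": (8, 44, 0, 0),
    "age_ge_65": (10, 36, 0, 0),
    "hypertension": (6, 33, 0, 0),
    "diabetes_mellitus": (3, 10, 0, 0),
    "chronic_heart_failure": (7, 25, 0, 0),
    "atrial_fibrillation": (17, 70, 0, 0),
    "myocardial_infarction": (2, 2, 0, 0),
    "ace_inhibitor": (2, 19, 2, 20),
    # H2/H2 diplotype indicator: 1/33 cases vs 20/109 among the rest
    "ace_h2h2": (1, 32, 0, 0),
}

#: Cohort-level covariate prevalences (generator defaults).
COVARIATE_PREVALENCES = {
    name: (a + b) / (N_TOTAL - ma - mb)
    for name, (a, b, ma, mb) in COVARIATE_GROUP_COUNTS.items()
    if name != "ace_h2h2"
}

#: Adjusted odds ratios of the final multivariable model (the three terms
#: surviving backward elimination).
ADJUSTED_OR = {
    "rs5050_carrier": 5.04,
    "rs2640543_carrier": 3.17,
    "ace_h2h2": 0.12,
}

#: Weighted-risk-score strata: (cases, controls) for the low (<=25th
#: percentile), middle and high (>=75th percentile) score groups, and the
#: published percentile cut points.
WRS_STRATA_COUNTS = ((1, 28), (13, 89), (7, 4))
WRS_PERCENTILE_CUTS = (2, 4)


def _place(n: int, n_one: int, n_missing: int, offset: int) -> np.ndarray:
    """Codes (1 exposed / 0 unexposed / -1 missing) over ``n`` slots, with
    the exposed block rotated by ``offset`` so that different columns do
    not pile their exposed subjects onto the same rows."""
    codes = np.zeros(n, dtype=np.int8)
    order = (np.arange(n) + offset) % n
    codes[order[:n_one]] = 1
    if n_missing:
        codes[order[n_one : n_one + n_missing]] = -1
    return codes


def _code_to_dosage(snp: SnpDef, codes: np.ndarray) -> np.ndarray:
    """Map exposure codes to a representative dosage: heterozygote for the
    exposed pole; the grouping-defining homozygote for the unexposed pole."""
    unexposed_dosage = 2 if snp.grouping == "variant_recessive" else 0
    dosage = np.where(codes == 1, 1, unexposed_dosage).astype(np.int8)
    dosage[codes == -1] = -1
    return dosage


def reconstruct_demo_cohort():
    """Rebuild a 142-subject demo cohort from the printed margins.

    Every per-column 2x2 (or missingness) margin equals the printed count
    exactly, so univariate tables, percentages, p-values and crude ORs are
    reproduced.  The joint distribution across columns is NOT published:
    exposed subjects are placed deterministically with a per-column
    rotation.  In particular the *ACE* genotype columns carry no haplotype
    structure — use the synthetic generator, not this demo, for EM/LD work.
    The H2/H2 diplotype indicator is therefore supplied directly as the
    phenotype column ``ace_h2h2``.

    Returns
    -------
    (GenotypeMatrix, PhenotypeTable)
    """
    subjects = [f"S{i + 1:03d}" for i in range(N_TOTAL)]
    snps = list(SNP_DEFS)
    dosage = np.empty((N_TOTAL, len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        ec, eo, uc, uo, mc, mo = GENOTYPE_GROUP_COUNTS[snp.snp_id]
        case_codes = _place(N_CASES, ec, mc, offset=3 * j)
        ctrl_codes = _place(N_CONTROLS, eo, mo, offset=7 * j)
        codes = np.concatenate([case_codes, ctrl_codes])
        dosage[:, j] = _code_to_dosage(snp, codes)
    gm = GenotypeMatrix(subjects=subjects, snps=snps, dosage=dosage)

    pheno = {"bleeding": np.r_[np.ones(N_CASES), np.zeros(N_CONTROLS)]}
    for j, (name, (a, b, mc, mo)) in enumerate(COVARIATE_GROUP_COUNTS.items()):
        case_codes = _place(N_CASES, a, mc, offset=5 * j)
        ctrl_codes = _place(N_CONTROLS, b, mo, offset=11 * j)
        col = np.concatenate([case_codes, ctrl_codes]).astype(float)
        col[col < 0] = np.nan
        pheno[name] = col
    df = pd.DataFrame(pheno, index=pd.Index(subjects, name="subject_id"))
    # reporting-only age consistent with the dichotomy
    df["age_years"] = np.where(df["age_ge_65"] == 1, 70.0, 55.0)
    pt = PhenotypeTable(df)
    return gm, pt


def demo_wrs_fixture():
    """Integer weighted-risk-score vector and outcome matching the published
    strata: 29 subjects at score 2 (1 case), 102 at score 3 (13 cases),
    11 at scores >= 4 (7 cases); cut points (2, 4)."""
    (lc, lo), (mc, mo), (hc, ho) = WRS_STRATA_COUNTS
    scores = np.r_[
        np.full(lc + lo, 2.0),
        np.full(mc + mo, 3.0),
        np.full(hc + ho - 3, 4.0),
        np.full(3, 5.0),
    ]
    outcome = np.r_[
        np.ones(lc), np.zeros(lo),
        np.ones(mc), np.zeros(mo),
        np.ones(hc), np.zeros(ho),
    ]
    # cases in the high stratum sit on both score values
    return scores, outcome
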