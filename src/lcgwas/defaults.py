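"""Default study conditions for the synthetic cohort generator.

These constants describe the bipolar-disorder case-control design the
package emulates: ~1000 cases and 1034 controls of European descent, ten
binary lifetime co-morbidity / psychotic-symptom indicators observed for
cases only, three latent co-morbidity classes, class-specific age and sex
distributions, and three planted rare recessive SNP effects whose
minor-allele homozygotes are confined to a single class.

Class order (index 0, 1, 2):

0. substance abuse and/or psychosis without alcohol dependence (26%)
1. alcohol dependence with broad co-morbidity (25%)
2. low co-morbidity (49%)
"""

from __future__ import annotations

import numpy as np

from .synthetic import CohortSpec, SNPSpec

__all__ = [
    "ITEM_NAMES",
    "CLASS_PROPORTIONS",
    "ENDORSEMENT_PROBS",
    "AGE_MEANS",
    "AGE_SDS",
    "FEMALE_PROBS",
    "PLANTED_SNPS",
    "BURDEN_ITEMS",
    "default_cohort_spec",
]

#: indicator items: substance abuse, obsessive-compulsive disorder, panic
#: disorder, social/specific phobia, eating disorder, ADHD, alcohol abuse,
#: alcohol dependence, nicotine dependence, psychotic symptoms
ITEM_NAMES = [
    "SUBA",
    "OCD",
    "PD",
    "SP",
    "ED",
    "ADHD",
    "ALCAB",
    "ALCDEP",
    "NIC",
    "PSYCH",
]

CLASS_PROPORTIONS = (0.26, 0.25, 0.49)

#: class-conditional endorsement probabilities (rows: classes, cols: items)
ENDORSEMENT_PROBS = np.array(
    [
        # SUBA  OCD    PD    SP    ED   ADHD  ALCAB ALCDEP  NIC  PSYCH
        [0.39, 0.17, 0.37, 0.24, 0.12, 0.15, 0.42, 0.00, 0.30, 0.40],
        [0.78, 0.10, 0.31, 0.23, 0.10, 0.20, 0.00, 1.00, 0.47, 0.29],
        [0.07, 0.03, 0.12, 0.08, 0.03, 0.01, 0.03, 0.18, 0.08, 0.17],
    ]
)

AGE_MEANS = (41.0, 41.0, 44.0)
AGE_SDS = (12.6, 10.8, 13.8)
FEMALE_PROBS = (0.62, 0.39, 0.49)

CONTROL_AGE_MEAN = 52.5
CONTROL_AGE_SD = 17.6
CONTROL_FEMALE_PROB = 502 / 1034

AGE_MISSING_RATE = 0.008  # ~8 of 1000 case ages missing

#: three rare recessive effects, each confined to one latent class: two for
#: the substance-abuse/psychosis class (4 homozygotes each) and one common-ish
#: variant for the alcohol-dependence class (46 homozygotes)
PLANTED_SNPS = [
    SNPSpec(
        snp_id="rs1039002",
        chromosome="6",
        position=166155457,
        maf=0.06,
        effect_class=0,
        effect_model="recessive",
        n_forced_carriers=4,
    ),
    SNPSpec(
        snp_id="rs12563333",
        chromosome="1",
        position=218724857,
        maf=0.03,
        effect_class=0,
        effect_model="recessive",
        n_forced_carriers=4,
    ),
    SNPSpec(
        snp_id="rs2727943",
        chromosome="3",
        position=1897973,
        maf=0.15,
        effect_class=1,
        effect_model="recessive",
        n_forced_carriers=46,
    ),
]

#: items counted as distinct co-morbid diagnoses for burden summaries;
#: psychotic symptoms are part of the index phenotype, not a co-morbidity
BURDEN_ITEMS = [n for n in ITEM_NAMES if n != "PSYCH"]


def default_cohort_spec(
    n_cases: int = 1000,
    n_controls: int = 1034,
    n_null_snps: int = 5000,
    with_planted_snps: bool = True,
    fst: float = 0.0,
    genotype_missing_rate: float = 0.005,
    seed: int = 0,
) -> CohortSpec:
    """The default simulated study: sample sizes, class structure and effects.

    The 0.5% genotype missing rate reflects the high post-QC call rate of a
    modern array after confidence filtering.  Structure (``fst``) is off by
    default because the emulated sample is a single self-reported ancestry
    group; turn it on to exercise stratification correction.
    """
    return CohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        class_proportions=CLASS_PROPORTIONS,
        endorsement_probs=ENDORSEMENT_PROBS.copy(),
        item_names=list(ITEM_NAMES),
        aux_age_means=AGE_MEANS,
        aux_age_sds=AGE_SDS,
        aux_female_probs=FEMALE_PROBS,
        control_age_mean=CONTROL_AGE_MEAN,
        control_age_sd=CONTROL_AGE_SD,
        control_female_prob=CONTROL_FEMALE_PROB,
        age_missing_rate=AGE_MISSING_RATE,
        snp_specs=list(PLANTED_SNPS) if with_planted_snps else [],
        n_null_snps=n_null_snps,
        null_maf_range=(0.01, 0.5),
        fst=fst,
        genotype_missing_rate=genotype_missing_rate,
        seed=seed,
    )
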