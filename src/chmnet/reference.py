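"""Published summary data for the 2010 Taiwan allergic-rhinitis cohort.

A nationwide claims-database study of allergic rhinitis (ICD-9-CM 477.9,
Taiwan, 2010) reported grouped counts for Chinese-herbal-medicine (CHM) users
versus nonusers, prevalence rankings of herbal formulas (HF) and single herbs
(SH), and a six-community co-prescription network.  The raw prescription
records are not publicly deposited, but the printed summary counts are, and
they serve two purposes here:

* exact re-computation of every published percentage and test statistic from
  the grouped counts (``chmnet.cohort``), and
* calibration of the synthetic claims-data generator
  (``chmnet.synthetic``), whose planted co-prescription communities and core
  herbs mirror the published network.

All counts below are grouped (per variable, per level); the underlying
patient-level joint distribution is unknown and is *not* encoded here.
"""

from __future__ import annotations

N_USERS = 33_507
N_NONUSERS = 55_641
N_SUBJECTS = N_USERS + N_NONUSERS  # 89,148
N_PRESCRIPTIONS = 222_279

# variable -> level -> (users count, nonusers count).  Flag variables carry a
# single "yes" level; their complement is implicit.
COHORT_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "gender": {
        "male": (14_607, 29_276),
        "female": (18_900, 26_365),
    },
    "age_band": {
        "0-20": (12_572, 22_941),
        "21-40": (10_350, 12_869),
        "41+": (10_585, 19_831),
    },
    "urbanization": {
        "1": (19_229, 33_689),
        "2": (11_362, 17_205),
        "3": (2_916, 4_747),
    },
    "insured_level": {
        "1-19999": (21_110, 37_326),
        "20000-39999": (8_485, 12_242),
        "40000+": (3_912, 6_073),
    },
    "atopic_dermatitis": {"yes": (5_957, 9_275)},
    "asthma": {"yes": (4_178, 9_836)},
    "chronic_sinusitis": {"yes": (1_311, 1_720)},
    "n_med_types": {
        "0": (5_097, 2_672),
        "1": (11_613, 21_234),
        "2": (10_691, 19_975),
        ">=3": (6_106, 11_761),
    },
}

# Variables whose levels exhaust the group (counts sum to the group size).
EXHAUSTIVE_VARIABLES = ("gender", "age_band", "urbanization", "insured_level", "n_med_types")
FLAG_VARIABLES = ("atopic_dermatitis", "asthma", "chronic_sinusitis")

# --------------------------------------------------------------------------
# Demo herb roster: the six published co-prescription communities.
#
# Community membership beyond the cores and the explicitly named members is
# not tabulated in the publication; the remaining members are plausible AR
# herbs assigned once for the synthetic fixture.  Selection weights put each
# core's expected prevalence at its published value (25.5%, 22.9%, 16.2%,
# 19.1% of prescriptions); the two isolated drug-pair communities have no
# published prevalence and are fixed at 6% each.
# --------------------------------------------------------------------------

DEMO_CLUSTERS: list[dict] = [
    {
        "label": "wind-heat",
        "core": "Xin-Yi-Qing-Fei-Tang",
        "herbs": [
            "Xin-Yi-Qing-Fei-Tang",
            "Houttuynia cordata",
            "Cang-Er-San",
            "Xanthium sibiricum",
            "Scutellaria baicalensis",
            "Mentha haplocalyx",
            "Gardenia jasminoides",
            "Eriobotrya japonica",
            "Cryptotympana pustulata",
            "Magnolia biondii",
        ],
        "weight": 0.255,
    },
    {
        "label": "wind-cold-dampness",
        "core": "Xiao-Qing-Long-Tang",
        "herbs": [
            "Xiao-Qing-Long-Tang",
            "Xin-Yi-San",
            "Xiang-Sha-Liu-Jun-Zi-Tang",
            "Ge-Gen-Tang",
            "Ma-Huang-Fu-Zi-Xi-Xin-Tang",
            "Zingiber officinale",
            "Asarum heterotropoides",
            "Cinnamomum cassia",
            "Ephedra sinica",
        ],
        "weight": 0.229,
    },
    {
        "label": "wind",
        "core": "Angelica dahurica",
        "herbs": [
            "Angelica dahurica",
            "Saposhnikovia divaricata",
            "Schizonepeta tenuifolia",
            "Ligusticum chuanxiong",
        ],
        "weight": 0.162,
    },
    {
        "label": "phlegm",
        "core": "Platycodon grandiflorum",
        "herbs": [
            "Platycodon grandiflorum",
            "Fritillaria thunbergii",
            "Prunus armeniaca",
            "Glycyrrhiza uralensis",
        ],
        "weight": 0.191,
    },
    {
        "label": "heat-toxin",
        "core": "Forsythia suspensa",
        "herbs": ["Forsythia suspensa", "Lonicera japonica"],
        "weight": 0.06,
    },
    {
        "label": "qi-stagnation",
        "core": "Jia-Wei-Xiao-Yao-San",
        "herbs": ["Jia-Wei-Xiao-Yao-San", "Cyperus rotundus"],
        "weight": 0.06,
    },
]

DEMO_BACKGROUND_HERBS: list[str] = [
    "Astragalus membranaceus",
    "Atractylodes macrocephala",
    "Bupleurum chinense",
    "Citrus reticulata",
    "Coix lacryma-jobi",
    "Dioscorea opposita",
    "Paeonia lactiflora",
    "Poria cocos",
    "Pinellia ternata",
    "Pueraria lobata",
    "Rehmannia glutinosa",
    "Salvia miltiorrhiza",
    "Schisandra chinensis",
    "Ziziphus jujuba",
    "Anemarrhena asphodeloides",
    "Ophiopogon japonicus",
    "Lilium brownii",
    "Cimicifuga heracleifolia",
    "Clematis armandii",
    "Camellia sinensis",
]

# Herbal formulas are concentrated premixtures (pinyin names); everything else
# in the roster is a single-herb preparation (botanical names).
DEMO_FORMULAS = frozenset(
    {
        "Xin-Yi-Qing-Fei-Tang",
        "Xiao-Qing-Long-Tang",
        "Xin-Yi-San",
        "Cang-Er-San",
        "Ge-Gen-Tang",
        "Xiang-Sha-Liu-Jun-Zi-Tang",
        "Ma-Huang-Fu-Zi-Xi-Xin-Tang",
        "Jia-Wei-Xiao-Yao-San",
    }
)


def demo_herb_type_map() -> dict[str, str]:
    """'HF' / 'SH' label for every herb in the demo roster."""
    herbs: list[str] = [h for c in DEMO_CLUSTERS for h in c["herbs"]] + DEMO_BACKGROUND_HERBS
    return {h: ("HF" if h in DEMO_FORMULAS else "SH") for h in herbs}


# Comparator (western-medicine) drug categories for allergic rhinitis: the
# published comparison used 39 drugs in four guideline categories, with
# category-level binding-protein pool sizes 55 / 32 / 7 / 29.
WM_CATEGORIES: dict[str, dict] = {
    "sympathomimetics": {"n_drugs": 12, "n_proteins": 55},
    "antihistamines": {"n_drugs": 15, "n_proteins": 32},
    "leukotriene receptor antagonists": {"n_drugs": 2, "n_proteins": 7},
    "glucocorticoids": {"n_drugs": 10, "n_proteins": 29},
}
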