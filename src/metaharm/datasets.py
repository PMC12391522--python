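"""Bundled example data.

``example_inventory_corpus`` reproduces the published cohort-by-group
variable-count breakdown of three large cardiovascular cohort studies (ARIC,
MESA and the Framingham Heart Study): 885 labeled variable descriptions over
7 concept groups. Only the counts are real — the records themselves are
synthetic placeholders (one stand-in concept per group, templated
descriptions), which is exactly enough to exercise inventory summaries, whose
arithmetic depends on counts alone.
"""

from __future__ import annotations

from .metadata_io import ConceptDictionary, ConceptEntry, Corpus, VariableRecord

# (cohort, group) -> number of labeled variables; totals: ARIC 315, MESA 161,
# FHS 409, grand total 885.
INVENTORY_COUNTS: dict[str, dict[str, int]] = {
    "ARIC": {
        "sociodemographics": 12,
        "vitals": 18,
        "comorbidities": 59,
        "laboratories": 32,
        "medications": 131,
        "diet": 42,
        "other": 21,
    },
    "MESA": {
        "sociodemographics": 11,
        "vitals": 10,
        "comorbidities": 76,
        "laboratories": 16,
        "medications": 30,
        "diet": 1,
        "other": 17,
    },
    "FHS": {
        "sociodemographics": 13,
        "vitals": 63,
        "comorbidities": 98,
        "laboratories": 49,
        "medications": 91,
        "diet": 74,
        "other": 21,
    },
}


def example_inventory_corpus() -> Corpus:
    """Synthetic stand-in corpus whose per-(cohort, group) counts match the
    published three-cohort inventory."""
    groups = list(next(iter(INVENTORY_COUNTS.values())))
    concepts = ConceptDictionary(
        ConceptEntry(f"g_{g}", f"placeholder {g} concept", g) for g in groups
    )
    records = []
    for cohort, by_group in INVENTORY_COUNTS.items():
        for g, n in by_group.items():
            for i in range(n):
                records.append(
                    VariableRecord(
                        cohort_id=cohort,
                        variable_name=f"{cohort.lower()}_{g}_{i:03d}",
                        description=f"{g} variable {i:03d} ({cohort} codebook)",
                        concept_id=f"g_{g}",
                    )
                )
    return Corpus(records=records, concepts=concepts)
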