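"""CNS region vocabulary and the fixed 13 -> 7 anatomical merge map.

The 13 sampled CNS territories collapse onto 7 non-overlapping regions by
pooling anatomically overlapping sub-regions (the two cerebellar samplings,
the three cortical samplings, the three basal-ganglia nuclei and the
amygdala/hippocampus pair). Specificity scores are always computed at the
7-region level so that a gene confined to several close sub-regions is not
artificially scored as broadly expressed.
"""

from __future__ import annotations

REGIONS_13: tuple[str, ...] = (
    "cerebellum",
    "cerebellar hemisphere",
    "cortex",
    "frontal cortex",
    "anterior cingulate cortex",
    "hypothalamus",
    "hippocampus",
    "spinal cord",
    "amygdala",
    "putamen",
    "caudate",
    "nucleus accumbens",
    "substantia nigra",
)

REGION_MERGE_MAP: dict[str, str] = {
    "cerebellum": "cerebellum",
    "cerebellar hemisphere": "cerebellum",
    "cortex": "cortex",
    "frontal cortex": "cortex",
    "anterior cingulate cortex": "cortex",
    "putamen": "basal ganglia",
    "nucleus accumbens": "basal ganglia",
    "caudate": "basal ganglia",
    "amygdala": "amygdala-hippocampus",
    "hippocampus": "amygdala-hippocampus",
    "hypothalamus": "hypothalamus",
    "spinal cord": "spinal cord",
    "substantia nigra": "substantia nigra",
}

# Lexicographic order; also the deterministic tie-break order for argmax ties.
REGIONS_7: tuple[str, ...] = tuple(sorted(set(REGION_MERGE_MAP.values())))

assert len(REGIONS_13) == 13
assert len(REGIONS_7) == 7


def merge_region(region_13: str) -> str:
    """Map one of the 13 territory names onto its merged 7-region name."""
    try:
        return REGION_MERGE_MAP[region_13]
    except KeyError:
        raise ValueError(f"unknown CNS region: {region_13!r}") from None
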