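"""Region parcellation used throughout the pipeline.

The analysis operates on 44 bihemispheric regions of a rat whole-brain
parcellation (SIGMA-derived), with a 12-region default mode network (DMN)
subset.  The synthetic generator additionally groups the regions into three
signal communities (a DMN/cortical community, a sensorimotor community and a
subcortical community) whose shared latent factors produce the modular
correlation structure the downstream graph analysis expects.
"""

from __future__ import annotations

# 44 bihemispheric regions, fixed order.
REGIONS: tuple[str, ...] = (
    "BF", "FrA", "OF", "PL", "IL", "Cing1", "Cing2", "aIns", "dyIns", "pIns",
    "Sept", "PreTe", "Amyg", "BNST", "Acb", "dStr", "M1", "M2", "S1", "S2",
    "Ect", "Ent", "Peri", "ParA", "TempA", "V1", "V2", "Aud1", "Aud2", "RS",
    "HypR", "CA1", "CA2", "CA3", "DG", "Sub", "Th", "Hb", "VTA", "IC", "SC",
    "PAG", "SN", "DRN",
)

N_REGIONS = len(REGIONS)

# Default mode network subset (12 regions, fixed order).
DMN_REGIONS: tuple[str, ...] = (
    "OF", "PL", "IL", "Cing1", "Cing2", "RS", "TempA", "ParA",
    "Aud1", "Aud2", "V1", "CA1",
)

# Serotonergic / hypothalamic hub regions whose coupling to cortex increases
# under psilocybin in the generative model.
HUB_REGIONS: tuple[str, ...] = ("HypR", "DRN")

# Signal communities of the synthetic generator.  The DMN/cortical community
# carries the treatment effect; the sensorimotor community is a built-in null.
COMMUNITY_DMN_CORTICAL: tuple[str, ...] = DMN_REGIONS + (
    "FrA", "aIns", "dyIns", "pIns", "Ect", "Ent", "Peri", "V2",
)
COMMUNITY_SENSORIMOTOR: tuple[str, ...] = ("M1", "M2", "S1", "S2", "IC", "SC", "PreTe")
COMMUNITY_SUBCORTICAL: tuple[str, ...] = (
    "BF", "Sept", "Amyg", "BNST", "Acb", "dStr", "HypR", "CA2", "CA3", "DG",
    "Sub", "Th", "Hb", "VTA", "PAG", "SN", "DRN",
)

COMMUNITIES: dict[str, tuple[str, ...]] = {
    "dmn_cortical": COMMUNITY_DMN_CORTICAL,
    "sensorimotor": COMMUNITY_SENSORIMOTOR,
    "subcortical": COMMUNITY_SUBCORTICAL,
}


def region_index(label: str) -> int:
    """Position of ``label`` in the fixed 44-region order."""
    try:
        return REGIONS.index(label)
    except ValueError:
        raise KeyError(f"unknown region label: {label!r}") from None


def indices(labels) -> list[int]:
    """Indices of a list of labels in the fixed region order."""
    return [region_index(lab) for lab in labels]


assert set(DMN_REGIONS) <= set(REGIONS)
assert sorted(
    COMMUNITY_DMN_CORTICAL + COMMUNITY_SENSORIMOTOR + COMMUNITY_SUBCORTICAL
) == sorted(REGIONS)
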