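"""Shared vocabularies for the plastics-to-health pipeline.

The model world is stratified by eight geographical archetypes (World Bank
income level x urban/rural), six global system scenarios, three municipal
plastics categories, and the lifecycle stages of the plastics value chain
from primary production to end of life.  Human-health impacts are carried
through eight health-related midpoint indicators and converted to endpoint
disability-adjusted life-years (DALYs).
"""

from __future__ import annotations

# The 8 health-related midpoint impact categories (ReCiPe-2016-style,
# hierarchic perspective, 100-year horizon).
MIDPOINTS: tuple[str, ...] = (
    "global_warming",
    "ozone_depletion",
    "ionising_radiation",
    "ozone_formation",
    "fine_pm",
    "carcinogenic_tox",
    "noncarcinogenic_tox",
    "water_use",
)

# Geographical archetypes: income level x settlement density, ordered from
# highest to lowest income rank.
ARCHETYPES: tuple[str, ...] = (
    "hi_urban",
    "hi_rural",
    "umi_urban",
    "umi_rural",
    "lmi_urban",
    "lmi_rural",
    "li_urban",
    "li_rural",
)

# Global system scenarios, in canonical reporting order.
SCENARIOS: tuple[str, ...] = (
    "bau",
    "current_commitments",
    "collect_dispose",
    "recycling",
    "reduce_substitute",
    "system_change",
)

# Municipal plastics categories.
CATEGORIES: tuple[str, ...] = (
    "rigid_mono",
    "flexible_mono",
    "multilayer_multi",
)

# Lifecycle stages of the plastics system.  Littering, informal collection
# and beach clean-up are zero-effect stages: mass routes through them but
# they carry empty inventories (human energy only).
STAGES: tuple[str, ...] = (
    "production",
    "collection",
    "informal_collection",
    "sorting",
    "mechanical_recycling_closed",
    "mechanical_recycling_open",
    "chemical_recycling",
    "incineration",
    "engineered_landfill",
    "dumpsite",
    "open_burning",
    "littering",
    "beach_cleanup",
    "aquatic_pollution",
    "terrestrial_pollution",
)

ZERO_EFFECT_STAGES: tuple[str, ...] = (
    "informal_collection",
    "littering",
    "beach_cleanup",
)

# Single-use substitute materials and reusable-glass systems.
SINGLE_USE_SUBSTITUTES: tuple[str, ...] = ("paper", "coated_paper", "polylactide")
REUSE_SYSTEMS: tuple[str, ...] = ("household_reuse", "door_to_door_refill")

# Emission bookkeeping.
COMPARTMENTS: tuple[str, ...] = ("air", "water", "soil", "groundwater")
TERMS: tuple[str, ...] = ("short", "long")

YEARS: tuple[int, int] = (2016, 2040)

# Directions of an impact record: induced burdens are positive, avoided
# burdens (recycling / waste-to-fuel credits) are negative.
DIRECTION_INDUCED = "induced"
DIRECTION_AVOIDED = "avoided"
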