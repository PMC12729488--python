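"""Behaviour label taxonomy and the post-processing regrouping scheme.

The classifier works on seven behavioural classes derived from collar-video
annotation of captive koalas; post-processing collapses them into four
ecological categories (plus a residual ``Other`` bucket) used for budgets,
ground-visit detection and diel modelling.
"""

from __future__ import annotations

# Seven-class model labels
BELLOWING = "Bellowing"
CLIMBING = "Climbing"
FEEDING = "Feeding"
GROOMING = "Grooming"
STILL = "Still"
IN_TREE_MOVEMENT = "In-tree Movement"
WALKING = "Walking"

MODEL_CLASSES: tuple[str, ...] = (
    BELLOWING,
    CLIMBING,
    FEEDING,
    GROOMING,
    STILL,
    IN_TREE_MOVEMENT,
    WALKING,
)

# Four final categories + residual
GENERAL_MOVEMENT = "General Movement in Tree"
MOTIONLESS = "Motionless in Tree"
FEEDING_GROOMING = "Feeding & Grooming in Tree"
OTHER = "Other"

CATEGORIES: tuple[str, ...] = (GENERAL_MOVEMENT, MOTIONLESS, FEEDING_GROOMING, WALKING)
CATEGORIES_WITH_OTHER: tuple[str, ...] = CATEGORIES + (OTHER,)

#: Deterministic many-to-one map from model classes to final categories.
#: Rare high-intensity classes fall into ``Other``; climbing and
#: undifferentiated in-tree movement merge into general movement.
REGROUP_MAP: dict[str, str] = {
    FEEDING: FEEDING_GROOMING,
    GROOMING: FEEDING_GROOMING,
    CLIMBING: GENERAL_MOVEMENT,
    IN_TREE_MOVEMENT: GENERAL_MOVEMENT,
    STILL: MOTIONLESS,
    WALKING: WALKING,
    BELLOWING: OTHER,
    # under-sampled raw annotations, if they survive to this stage
    "Bounding": OTHER,
    "Rapid Climbing Up": OTHER,
    "Body Shake": OTHER,
}

#: Model classes whose signal is generated while the animal is in a tree;
#: canopy-sway contamination applies only to these.
IN_TREE_CLASSES: frozenset[str] = frozenset(
    {BELLOWING, CLIMBING, FEEDING, GROOMING, STILL, IN_TREE_MOVEMENT}
)

#: Sentinel used for missing/unscored seconds in label series.
MISSING = ""


def regroup_label(label: str) -> str:
    """Map one seven-class label to its final category.

    Raises ``KeyError`` for labels outside the known taxonomy.
    """
    return REGROUP_MAP[label]
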