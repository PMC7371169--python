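"""The fixed eight-class behaviour catalogue used throughout the pipeline.

Behaviour names are plain strings; this module is the single source of truth
for the class list, its canonical (lexicographic) ordering, and the standard
coarse partition into passive / locomotion / feeding super-classes.
"""

from __future__ import annotations

BEHAVIOURS: tuple[str, ...] = (
    "lay",
    "sit",
    "stand",
    "walk",
    "trot",
    "run",
    "eat",
    "drink",
)

PASSIVE: frozenset[str] = frozenset({"lay", "sit", "stand"})
LOCOMOTION: frozenset[str] = frozenset({"walk", "trot", "run"})
FEEDING: frozenset[str] = frozenset({"eat", "drink"})

#: Coarse merge map used by the transfer-confusion experiment: passive
#: postures collapse to one class, feeding behaviours to another, and each
#: gait keeps its own class.
DEFAULT_MERGE_MAP: dict[str, tuple[str, ...]] = {
    "passive": ("lay", "sit", "stand"),
    "walk": ("walk",),
    "trot": ("trot",),
    "run": ("run",),
    "feeding": ("eat", "drink"),
}


def sorted_classes(labels) -> tuple[str, ...]:
    """Canonical (lexicographic) ordering of the distinct labels present."""
    return tuple(sorted(set(labels)))


def chance_level(n_classes: int) -> float:
    """Accuracy of uniform guessing over ``n_classes`` classes (1/K)."""
    if n_classes < 1:
        raise ValueError(f"n_classes must be >= 1, got {n_classes}")
    return 1.0 / n_classes
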