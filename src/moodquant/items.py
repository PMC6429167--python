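"""Q-Log item vocabulary.

The Q-Log diary presents 40 mood adjectives drawn from the Profile of Mood
States short form, each rated on a 1-100 visual-analog slider with five
verbal anchors (not at all / a little / moderately / quite a bit /
extremely) spaced 25 points apart.  The adjectives group into seven mood
categories.  The vocabulary below is this package's canonical instrument:
item order is fixed and shared by the synthetic generator, the diary
reader and the PCA stage.
"""

from __future__ import annotations

# category -> adjectives; totals 40 items across the 7 POMS-SF categories
CATEGORY_ITEMS: dict[str, tuple[str, ...]] = {
    "tension-anxiety": ("tense", "on_edge", "uneasy", "restless", "anxious"),
    "depression-dejection": (
        "sad",
        "unworthy",
        "discouraged",
        "lonely",
        "gloomy",
        "hopeless",
        "helpless",
        "miserable",
    ),
    "anger-hostility": (
        "angry",
        "grouchy",
        "annoyed",
        "resentful",
        "bitter",
        "furious",
        "irritable",
    ),
    "fatigue-inertia": ("worn_out", "fatigued", "exhausted", "sluggish", "weary"),
    "confusion-bewilderment": (
        "confused",
        "distracted",
        "muddled",
        "bewildered",
        "forgetful",
    ),
    "vigor-activity": ("lively", "active", "energetic", "cheerful", "alert", "vigorous"),
    "self-mood": ("calm", "content", "stable_mood", "self_assured"),
}

#: Fixed 40-item order: categories in the order above, items in listed order.
ITEM_NAMES: tuple[str, ...] = tuple(
    name for items in CATEGORY_ITEMS.values() for name in items
)

#: item name -> category
ITEM_CATEGORY: dict[str, str] = {
    name: cat for cat, items in CATEGORY_ITEMS.items() for name in items
}

N_ITEMS = len(ITEM_NAMES)
assert N_ITEMS == 40

#: Slider anchor points on the 100-point scale (five verbal levels, 25 apart).
ANCHOR_POINTS: tuple[int, ...] = (0, 25, 50, 75, 100)

#: Categories whose items score higher when mood worsens.  Vigor items move
#: the opposite way; self-mood items are treated as inverse (calm/content
#: fall as depression deepens).
NEGATIVE_MOOD_CATEGORIES: frozenset[str] = frozenset(
    {
        "tension-anxiety",
        "depression-dejection",
        "anger-hostility",
        "fatigue-inertia",
        "confusion-bewilderment",
    }
)

DEPRESSION_ITEMS: tuple[str, ...] = CATEGORY_ITEMS["depression-dejection"]


def depression_item_indices() -> list[int]:
    """Column indices of the depression-dejection items in ITEM_NAMES order."""
    return [i for i, n in enumerate(ITEM_NAMES) if ITEM_CATEGORY[n] == "depression-dejection"]
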