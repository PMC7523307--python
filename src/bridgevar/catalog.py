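"""Item catalog: the momentary mental-state items and their cluster membership.

The analysis tracks seven momentary mental states measured on a 1-7 Likert
scale.  Each item belongs to the depression cluster (``DEP``), the anxiety
cluster (``ANX``), or to both (an *overlapping* item).  Two items are worded
positively on the questionnaire ("cheerful", "relaxed") and are reverse coded
before analysis so that high scores always mean worse mood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEP = "DEP"
ANX = "ANX"

__all__ = ["Item", "ItemCatalog", "default_catalog", "DEP", "ANX"]


@dataclass(frozen=True)
class Item:
    """One momentary mental-state item.

    Parameters
    ----------
    code : str
        Short unique code, e.g. ``"WOR"``.
    label : str
        Human-readable wording of the item.
    membership : frozenset of {"DEP", "ANX"}
        Symptom cluster(s) the item belongs to.  Items in both clusters are
        "overlapping" states and are the a-priori bridge candidates.
    reverse_coded : bool
        True when the raw questionnaire score must be flipped (``8 - x``)
        so that higher means more symptomatic.
    """

    code: str
    label: str
    membership: frozenset
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        m = frozenset(self.membership)
        if not m or not m <= {DEP, ANX}:
            raise ValueError(
                f"item {self.code!r}: membership must be a nonempty subset "
                f"of {{DEP, ANX}}, got {set(self.membership)}"
            )
        object.__setattr__(self, "membership", m)

    @property
    def overlapping(self) -> bool:
        return len(self.membership) == 2


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered collection of items; the column order of every panel/matrix."""

    items: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        items = tuple(self.items)
        codes = [it.code for it in items]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate item codes: {codes}")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def codes(self) -> list:
        return [it.code for it in self.items]

    def index(self, code: str) -> int:
        for i, it in enumerate(self.items):
            if it.code == code:
                return i
        raise KeyError(f"unknown item code {code!r}; known: {self.codes}")

    def __getitem__(self, code: str) -> Item:
        return self.items[self.index(code)]

    @property
    def reverse_coded_codes(self) -> list:
        return [it.code for it in self.items if it.reverse_coded]

    @property
    def overlapping_codes(self) -> list:
        return [it.code for it in self.items if it.overlapping]


def default_catalog() -> ItemCatalog:
    """The seven-item depression/anxiety catalog.

    Three pure depression items (listless, down, not-cheerful), two pure
    anxiety items (nervous, not-relaxed) and two overlapping items
    (worrying, irritated).  "Cheerful" and "relaxed" are asked positively
    and carry the reverse-coding flag.
    """
    both = frozenset({DEP, ANX})
    return ItemCatalog(
        items=(
            Item("REL", "I do not feel relaxed", frozenset({ANX}), reverse_coded=True),
            Item("CHE", "I do not feel cheerful", frozenset({DEP}), reverse_coded=True),
            Item("IRR", "I feel irritated", both),
            Item("LIS", "I feel listless", frozenset({DEP})),
            Item("DOW", "I feel down", frozenset({DEP})),
            Item("NER", "I feel nervous", frozenset({ANX})),
            Item("WOR", "I worry a lot", both),
        )
    )
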