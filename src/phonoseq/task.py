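"""Full-factorial consonant-sequence task designs.

Conditions are ordered consonant sequences embedded in a fixed-vowel
template (e.g. C₁VC₂VC₃ with vowel /AH/).  Sequence *position* always means
consonant slot and is 1-based throughout the public interface, matching the
C₁VC₂VC₃ convention used when talking about "1st/2nd/3rd position".

Consonant tokens are opaque ARPABET strings; no phonetic feature system is
modeled.  The same machinery serves real-word sequence designs by using word
strings as the "inventory".
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

from .exceptions import DesignError, LabelError

#: canonical templates for n consonant slots (alternating C and V, fixed vowel)
_TEMPLATES = {1: "CV", 2: "CVC", 3: "CVCVC", 4: "CVCVCVCV"}

REST_TEMPLATE = "REST"


def default_template(n_slots: int) -> str:
    return _TEMPLATES.get(n_slots, f"C{n_slots}")


@dataclass(frozen=True)
class ConditionLabel:
    """One task condition: an ordered consonant sequence plus segmentation.

    ``segmentation`` lists word-boundary indices into the consonant slots:
    a boundary at ``b`` means the first word covers slots ``1..b``.  Empty
    segmentation = a single word.
    """

    consonants: tuple[str, ...]
    vowel: str = "AH"
    segmentation: tuple[int, ...] = ()
    template: str = field(default="")

    def __post_init__(self):
        object.__setattr__(self, "consonants", tuple(self.consonants))
        object.__setattr__(self, "segmentation", tuple(self.segmentation))
        if not self.template:
            object.__setattr__(
                self, "template", default_template(len(self.consonants))
            )
        n = len(self.consonants)
        if self.template == REST_TEMPLATE:
            if n:
                raise LabelError("rest label must have no consonants")
            return
        prev = 0
        for b in self.segmentation:
            if not (0 < b < n):
                raise LabelError(
                    f"segmentation index {b} not interior to {n} slots"
                )
            if b <= prev:
                raise LabelError("segmentation indices must strictly increase")
            prev = b

    # -- derived ---------------------------------------------------------
    @property
    def length_class(self) -> int:
        """Number of consonant slots."""
        return len(self.consonants)

    @property
    def is_rest(self) -> bool:
        return self.template == REST_TEMPLATE

    @property
    def n_words(self) -> int:
        return len(self.segmentation) + 1

    def consonant_at(self, position: int) -> str:
        """Consonant in 1-based sequence position."""
        if not 1 <= position <= self.length_class:
            raise IndexError(
                f"position {position} out of range 1..{self.length_class}"
            )
        return self.consonants[position - 1]

    @property
    def key(self) -> str:
        """Stable string identifier, e.g. ``K.N.SH`` or ``K.N|SH.K``."""
        if self.is_rest:
            return "REST"
        parts = []
        prev = 0
        bounds = list(self.segmentation) + [self.length_class]
        for b in bounds:
            parts.append(".".join(self.consonants[prev:b]))
            prev = b
        return "|".join(parts)

    def spelled(self) -> str:
        """Human-readable form, e.g. ``KahNahSH`` / ``KahNah SHahKah``."""
        if self.is_rest:
            return "(rest)"
        v = self.vowel.lower().replace("ah", "ah")
        v = "ah" if self.vowel.upper() == "AH" else self.vowel.lower()
        words = []
        prev = 0
        for b in list(self.segmentation) + [self.length_class]:
            chunk = ""
            for i in range(prev, b):
                chunk += self.consonants[i]
                # trailing vowel except after a word-final consonant in
                # odd templates (CVC, CVCVC): follow the template string
                chunk += v
            words.append(chunk)
            prev = b
        return " ".join(words)

    def to_dict(self) -> dict:
        return {
            "consonants": list(self.consonants),
            "vowel": self.vowel,
            "segmentation": list(self.segmentation),
            "template": self.template,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionLabel":
        return cls(
            consonants=tuple(d["consonants"]),
            vowel=d.get("vowel", "AH"),
            segmentation=tuple(d.get("segmentation", ())),
            template=d.get("template", ""),
        )


REST = ConditionLabel(consonants=(), template=REST_TEMPLATE)


@dataclass(frozen=True)
class ConditionSet:
    """An ordered collection of unique conditions over one inventory."""

    inventory: tuple[str, ...]
    conditions: tuple[ConditionLabel, ...]
    includes_rest: bool = False
    vowel: str = "AH"

    def __post_init__(self):
        object.__setattr__(self, "inventory", tuple(self.inventory))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        keys = [c.key for c in self.conditions]
        if len(set(keys)) != len(keys):
            raise DesignError("conditions are not unique")
        inv = set(self.inventory)
        for c in self.conditions:
            if not set(c.consonants) <= inv:
                raise LabelError(
                    f"condition {c.key} uses tokens outside inventory {inv}"
                )

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    @property
    def keys(self) -> list[str]:
        return [c.key for c in self.conditions]

    def by_key(self, key: str) -> ConditionLabel:
        for c in self.conditions:
            if c.key == key:
                return c
        raise LabelError(f"no condition with key {key!r}")

    @property
    def length_classes(self) -> tuple[int, ...]:
        return tuple(sorted({c.length_class for c in self.conditions}))

    def union(self, other: "ConditionSet") -> "ConditionSet":
        """Concatenate two sets sharing an inventory (e.g. length series)."""
        if tuple(other.inventory) != self.inventory:
            raise DesignError("cannot union sets with different inventories")
        return ConditionSet(
            inventory=self.inventory,
            conditions=self.conditions + other.conditions,
            includes_rest=self.includes_rest or other.includes_rest,
            vowel=self.vowel,
        )

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "inventory": list(self.inventory),
                "vowel": self.vowel,
                "includes_rest": self.includes_rest,
                "conditions": [c.to_dict() for c in self.conditions],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, doc: str) -> "ConditionSet":
        d = json.loads(doc)
        return cls(
            inventory=tuple(d["inventory"]),
            conditions=tuple(
                ConditionLabel.from_dict(c) for c in d["conditions"]
            ),
            includes_rest=d.get("includes_rest", False),
            vowel=d.get("vowel", "AH"),
        )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_full_factorial(
    inventory,
    n_slots: int,
    template: str | None = None,
    vowel: str = "AH",
    include_rest: bool = False,
) -> ConditionSet:
    """All ``|inventory|**n_slots`` ordered sequences, lexicographic order.

    Order is deterministic: slot-major product in declared inventory order,
    so condition indices are reproducible across runs.
    """
    inventory = tuple(inventory)
    if not inventory:
        raise DesignError("inventory is empty")
    if n_slots < 1:
        raise DesignError(f"n_slots must be >= 1, got {n_slots}")
    conds = [
        ConditionLabel(consonants=combo, vowel=vowel,
                       template=template or default_template(n_slots))
        for combo in itertools.product(inventory, repeat=n_slots)
    ]
    if include_rest:
        conds.append(REST)
    return ConditionSet(
        inventory=inventory,
        conditions=tuple(conds),
        includes_rest=include_rest,
        vowel=vowel,
    )


def build_length_series(
    inventory, lengths, vowel: str = "AH"
) -> ConditionSet:
    """Union of full-factorial sets over several sequence lengths."""
    lengths = sorted(set(int(x) for x in lengths))
    if not lengths:
        raise DesignError("no lengths given")
    out = build_full_factorial(inventory, lengths[0], vowel=vowel)
    for n in lengths[1:]:
        out = out.union(build_full_factorial(inventory, n, vowel=vowel))
    return out


def build_word_boundary_set(
    inventory, n_slots: int, boundary_slot: int, vowel: str = "AH"
) -> ConditionSet:
    """Each factorial sequence twice: as one word and split at a boundary.

    The one-word and two-word partners share identical consonants and differ
    only in phonological word segmentation; total = 2 * |inventory|**n_slots.
    """
    inventory = tuple(inventory)
    if n_slots < 2:
        raise DesignError("word-boundary sets need n_slots >= 2")
    if not (0 < boundary_slot < n_slots):
        raise DesignError(
            f"boundary slot {boundary_slot} not interior to {n_slots} slots"
        )
    base = build_full_factorial(inventory, n_slots, vowel=vowel)
    conds = []
    for c in base:
        conds.append(c)
        conds.append(replace(c, segmentation=(boundary_slot,)))
    return ConditionSet(
        inventory=inventory, conditions=tuple(conds), vowel=vowel
    )


def single_position_pairs(
    cset: ConditionSet, position: int
) -> list[tuple[ConditionLabel, ConditionLabel]]:
    """Unordered condition pairs differing only at one 1-based position.

    Pairs agree at every other slot and in segmentation.  Output order is
    deterministic: by fixed context (set order), then pair lexicographic.
    """
    eligible = [
        c for c in cset.conditions
        if not c.is_rest and c.length_class >= position
    ]
    if position < 1 or not eligible:
        raise IndexError(f"position {position} out of range for this set")
    groups: dict[tuple, list[ConditionLabel]] = {}
    for c in eligible:
        ctx = (
            c.length_class,
            c.segmentation,
            c.consonants[: position - 1],
            c.consonants[position:],
        )
        groups.setdefault(ctx, []).append(c)
    pairs = []
    for ctx in groups.values():
        for a, b in itertools.combinations(ctx, 2):
            pairs.append((a, b))
    return pairs


def late_position_pair_contexts(
    cset: ConditionSet, shared_slots: int = 2
) -> dict[tuple, list[tuple[ConditionLabel, ConditionLabel]]]:
    """Pairs sharing the first ``shared_slots`` consonants, differing later.

    Returns, separately per segmentation context (one-word / two-word...),
    all unordered pairs that agree in slots ``1..shared_slots`` and differ in
    at least one later slot.  Used by the word-boundary truncation analysis.
    """
    by_ctx: dict[tuple, dict[tuple, list[ConditionLabel]]] = {}
    for c in cset.conditions:
        if c.is_rest or c.length_class <= shared_slots:
            continue
        prefix = c.consonants[:shared_slots]
        by_ctx.setdefault(c.segmentation, {}).setdefault(prefix, []).append(c)
    out: dict[tuple, list] = {}
    for seg, prefixes in by_ctx.items():
        pairs = []
        for group in prefixes.values():
            for a, b in itertools.combinations(group, 2):
                if a.consonants[shared_slots:] != b.consonants[shared_slots:]:
                    pairs.append((a, b))
        out[seg] = pairs
    return out
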