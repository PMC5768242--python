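"""Geometry of a 1-3-3-1 directional DBS lead.

The leads modelled here carry eight contacts on four levels: a ventral ring
(contact 1, level 1), two segmented levels of three contacts each spaced
120 degrees apart (contacts 2/3/4 on level 2, contacts 5/6/7 on level 3),
and a dorsal ring (contact 8, level 4).  Segment angles are abstract labels
(0/120/240); physical orientation in the skull is not modelled -- the
analysis only ever needs *relative* direction between contacts and a
putative beta source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

RING = "ring"

__all__ = [
    "RING",
    "Contact",
    "DirectionalLead",
    "angular_distance",
    "circular_distance_deg",
    "default_lead",
]


@dataclass(frozen=True)
class Contact:
    """A single electrode contact.

    Parameters
    ----------
    id : int
        Contact number, 1-8.
    level : int
        Ring level, 1 (most ventral) to 4 (most dorsal).
    angle_deg : float or "ring"
        Angular position of a segment in degrees, or :data:`RING` for the
        non-segmented ring contacts.
    """

    id: int
    level: int
    angle_deg: float | str

    @property
    def is_segmented(self) -> bool:
        return self.angle_deg != RING


def circular_distance_deg(a: float, b: float) -> float:
    """Smallest angle between two directions, in [0, 180] degrees."""
    d = abs(float(a) - float(b)) % 360.0
    return min(d, 360.0 - d)


def angular_distance(a: Contact, b: Contact) -> float:
    """Angular separation between two *segmented* contacts.

    Raises
    ------
    ValueError
        If either contact is a ring contact (rings have no direction).
    """
    for c in (a, b):
        if not c.is_segmented:
            raise ValueError(
                f"contact {c.id} is a ring contact and has no angular position"
            )
    return circular_distance_deg(a.angle_deg, b.angle_deg)


class DirectionalLead:
    """An ordered set of 8 contacts: 2 rings plus 6 segments on 2 levels."""

    def __init__(self, contacts: Sequence[Contact]):
        contacts = tuple(contacts)
        if len(contacts) != 8:
            raise ValueError(f"a directional lead has 8 contacts, got {len(contacts)}")
        seg = [c for c in contacts if c.is_segmented]
        rings = [c for c in contacts if not c.is_segmented]
        if len(seg) != 6 or len(rings) != 2:
            raise ValueError(
                f"expected 6 segmented and 2 ring contacts, got {len(seg)}/{len(rings)}"
            )
        for level in {c.level for c in seg}:
            angles = sorted(c.angle_deg for c in seg if c.level == level)
            if len(angles) != 3 or len(set(angles)) != 3:
                raise ValueError(f"level {level} must carry 3 distinct segment angles")
        self.contacts = contacts
        self._by_id = {c.id: c for c in contacts}

    @property
    def segmented_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.contacts if c.is_segmented)

    def contact(self, contact_id: int) -> Contact:
        try:
            return self._by_id[contact_id]
        except KeyError:
            raise KeyError(f"no contact with id {contact_id}") from None

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """Pairs of segments on adjacent levels sharing the same angle.

        These partition the six segments into three pairs; segments of a
        pair face the same direction and see correlated beta activity from
        a common source.
        """
        seg = [c for c in self.contacts if c.is_segmented]
        levels = sorted({c.level for c in seg})
        lo = {c.angle_deg: c.id for c in seg if c.level == levels[0]}
        hi = {c.angle_deg: c.id for c in seg if c.level == levels[1]}
        return [(lo[a], hi[a]) for a in sorted(lo) if a in hi]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"id": c.id, "level": c.level, "angle_deg": c.angle_deg}
                for c in self.contacts
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DirectionalLead":
        return cls(
            [Contact(d["id"], d["level"], d["angle_deg"]) for d in json.loads(text)]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"DirectionalLead(segments={self.segmented_ids})"


def default_lead() -> DirectionalLead:
    """The standard 1-3-3-1 layout: segments at 0/120/240 on levels 2 and 3.

    Contacts 2 and 5, 3 and 6, 4 and 7 are aligned (same angle, adjacent
    levels).
    """
    return DirectionalLead(
        [
            Contact(1, 1, RING),
            Contact(2, 2, 0.0),
            Contact(3, 2, 120.0),
            Contact(4, 2, 240.0),
            Contact(5, 3, 0.0),
            Contact(6, 3, 120.0),
            Contact(7, 3, 240.0),
            Contact(8, 4, RING),
        ]
    )
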