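"""Vertical tree compartments and their canonical ordering.

Trees are divided, from the ground up, into six compartments: the stump
(``Stu``, below the felling cut), the stem base (``Ste_b``, the lowest metres
of trunk, often deformed by buttresses and absent from some trees), the
well-conformed stem (``Ste``), and large, medium and small branches
(``LB``, ``MB``, ``SB`` -- basal diameter > 20 cm, 20-5 cm and < 5 cm).
All vertical-profile code indexes compartments in this order.
"""

from __future__ import annotations

#: Canonical bottom-to-top compartment order.
COMPARTMENTS: tuple[str, ...] = ("Stu", "Ste_b", "Ste", "LB", "MB", "SB")

#: Compartment -> vertical rank (Stu=0 ... SB=5).
RANK: dict[str, int] = {c: i for i, c in enumerate(COMPARTMENTS)}

STUMP = "Stu"
STEM_BASE = "Ste_b"
STEM = "Ste"
SMALL_BRANCH = "SB"


def validate_compartment(name: str) -> str:
    """Return *name* if it is a known compartment label, else raise ValueError."""
    if name not in RANK:
        raise ValueError(
            f"unknown compartment {name!r}; expected one of {COMPARTMENTS}"
        )
    return name
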