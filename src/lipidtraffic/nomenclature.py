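"""Shorthand (sum-composition) lipid nomenclature.

Direct-infusion lipidomics reports species as ``CLASS(C:D)`` — a head-group
class token followed by the total number of acyl-chain carbons and the total
number of carbon-carbon double bonds, e.g. ``TG(52:3)``, ``PC(36:4)``,
``SM(39:1)``.  Individual chains and sn-positions are not resolved at this
level, so chain parity is defined on the *total* carbon count: ``SM(39:1)``
is an odd-chain species because 39 is odd, regardless of how the carbons are
split between its chains.

This module parses such names into :class:`LipidSpecies` records, provides a
canonical serialisation and sort order, and decides whether a di- or
mono-glyceride is plausibly a fragment of a triglyceride in a given inventory
(loss of one or two acyl chains).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "KNOWN_CLASSES",
    "LipidParseError",
    "LipidSpecies",
    "parse_lipid_name",
    "flag_tg_derived",
    "sort_key",
]

#: Class tokens recognised by the pipeline; anything else becomes ``"other"``.
KNOWN_CLASSES = (
    "TG", "DG", "MG", "PC", "PE", "PS", "PI", "PG", "PA",
    "SM", "CE", "LPC", "LPE", "FA",
)

# Acyl-chain plausibility window for TG-fragment detection, per lost chain:
# a single biological acyl chain of 10-26 carbons carrying 0-6 double bonds.
ACYL_CARBON_RANGE = (10, 26)
ACYL_DOUBLE_BOND_RANGE = (0, 6)


class LipidParseError(ValueError):
    """Raised when a lipid name has no parseable ``(C:D)`` core."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid variable identified at sum-composition level.

    Attributes
    ----------
    raw_name:
        The name exactly as given in the input table.
    lipid_class:
        One of :data:`KNOWN_CLASSES` or ``"other"``.
    total_carbons:
        Sum of acyl-chain carbons (the ``C`` in ``CLASS(C:D)``).
    double_bonds:
        Sum of acyl-chain double bonds (the ``D``).
    adduct:
        Optional adduct / annotation text found around the core, stored
        verbatim and ignored for classification (e.g. chloride adducts).
    """

    raw_name: str
    lipid_class: str
    total_carbons: int
    double_bonds: int
    adduct: str | None = None
    odd_chain: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "odd_chain", self.total_carbons % 2 == 1)

    @property
    def canonical_name(self) -> str:
        """Canonical ``CLASS(C:D)`` serialisation (adduct dropped)."""
        return f"{self.lipid_class}({self.total_carbons}:{self.double_bonds})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


# CLASS token, "(C:D" core, optional non-numeric annotation after a comma or
# semicolon inside the parentheses, ")" and optional trailing adduct text.
_NAME_RE = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z][A-Za-z0-9\-]*?)     # class token
        \s*\(\s*
        (?P<c>\d+)\s*:\s*(?P<d>\d+)          # C:D core
        (?:\s*[,;]\s*(?P<inner>[^)]*?))?     # optional inner annotation
        \s*\)\s*
        (?P<trailing>\S.*?)?                 # optional trailing adduct text
        \s*$""",
    re.VERBOSE,
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Class tokens are matched case-insensitively and surrounding whitespace is
    tolerated.  Unrecognised class tokens map to ``lipid_class="other"`` as
    long as the ``(C:D)`` core is present; a name with no such core raises
    :class:`LipidParseError`.

    >>> parse_lipid_name("TG(52:3)").lipid_class
    'TG'
    >>> parse_lipid_name("SM(39:1)").odd_chain
    True
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError("lipid name must be non-empty text")
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidParseError(
            f"cannot parse lipid name {name!r}: no '(C:D)' core found"
        )
    cls_token = m.group("cls").upper()
    lipid_class = cls_token if cls_token in KNOWN_CLASSES else "other"
    carbons = int(m.group("c"))
    double_bonds = int(m.group("d"))
    if lipid_class != "other" and carbons == 0:
        raise LipidParseError(
            f"cannot parse lipid name {name!r}: zero carbons for class {lipid_class}"
        )
    pieces = [p for p in (m.group("inner"), m.group("trailing")) if p]
    adduct = " ".join(p.strip() for p in pieces) or None
    return LipidSpecies(
        raw_name=name,
        lipid_class=lipid_class,
        total_carbons=carbons,
        double_bonds=double_bonds,
        adduct=adduct,
    )


def sort_key(species: LipidSpecies) -> tuple[str, int, int, str]:
    """Canonical variable order: class, carbons, double bonds, raw name."""
    return (
        species.lipid_class,
        species.total_carbons,
        species.double_bonds,
        species.raw_name,
    )


def flag_tg_derived(
    glyceride: LipidSpecies,
    tg_inventory: Iterable[LipidSpecies],
    *,
    acyl_carbon_range: tuple[int, int] = ACYL_CARBON_RANGE,
    acyl_double_bond_range: tuple[int, int] = ACYL_DOUBLE_BOND_RANGE,
) -> bool:
    """Return True if a DG/MG is plausibly derived from a TG in the inventory.

    A diglyceride is linked to a triglyceride when the carbon and double-bond
    differences are consistent with the loss of one plausible acyl chain; a
    monoglyceride when consistent with the loss of two (the per-chain window
    is scaled by the number of lost chains).  Adding species to the inventory
    can only turn the answer from False to True, never the reverse.
    """
    if glyceride.lipid_class == "DG":
        lost_chains = 1
    elif glyceride.lipid_class == "MG":
        lost_chains = 2
    else:
        raise ValueError(
            f"flag_tg_derived expects a DG or MG, got {glyceride.lipid_class} "
            f"({glyceride.raw_name!r})"
        )
    c_lo, c_hi = acyl_carbon_range
    d_lo, d_hi = acyl_double_bond_range
    for tg in tg_inventory:
        if tg.lipid_class != "TG":
            raise ValueError(
                f"tg_inventory must contain TG species only, got {tg.raw_name!r}"
            )
        dc = tg.total_carbons - glyceride.total_carbons
        dd = tg.double_bonds - glyceride.double_bonds
        if (
            lost_chains * c_lo <= dc <= lost_chains * c_hi
            and lost_chains * d_lo <= dd <= lost_chains * d_hi
        ):
            return True
    return False
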