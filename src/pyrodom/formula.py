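"""Molecular formulas over the CHONSP element space.

A :class:`MolecularFormula` is an immutable record of element counts with a
charge convention (0 = neutral, the default; the charge only enters the
nominal-oxidation-state calculation downstream).  Monoisotopic mass, the
ring-and-double-bond equivalent (RDBE) and the canonical Hill string are
derived, never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .constants import ELEMENT_MASS

__all__ = ["MolecularFormula"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FIELD_BY_ELEMENT = {"C": "c", "H": "h", "N": "n", "O": "o", "P": "p", "S": "s"}


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts C/H/O/N/S/P of one molecular formula.

    Parameters
    ----------
    c, h, o, n, s, p
        Non-negative element counts; at least one carbon is required.
    charge
        Integer charge ``z`` (default 0, neutral).  Masses are always the
        neutral element-mass dot product; deprotonation bookkeeping is done
        by the ion/neutral conversion helpers, not here.
    """

    c: int
    h: int
    o: int = 0
    n: int = 0
    s: int = 0
    p: int = 0
    charge: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("formula must contain at least one carbon (c >= 1)")
        for name in ("h", "o", "n", "s", "p"):
            if getattr(self, name) < 0:
                raise ValueError(f"element count {name!r} must be non-negative")

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da (element-mass dot product)."""
        m = ELEMENT_MASS
        return (
            self.c * m["C"]
            + self.h * m["H"]
            + self.o * m["O"]
            + self.n * m["N"]
            + self.s * m["S"]
            + self.p * m["P"]
        )

    @property
    def rdbe(self) -> float:
        """Ring-and-double-bond equivalents: C - H/2 + N/2 + P/2 + 1."""
        return self.c - self.h / 2 + self.n / 2 + self.p / 2 + 1

    @property
    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then N/O/P/S alphabetically."""
        parts = []
        for el in ("C", "H", "N", "O", "P", "S"):
            count = getattr(self, _FIELD_BY_ELEMENT[el])
            if count == 1:
                parts.append(el)
            elif count > 1:
                parts.append(f"{el}{count}")
        return "".join(parts)

    @property
    def hc(self) -> float:
        return self.h / self.c

    @property
    def oc(self) -> float:
        return self.o / self.c

    def shift(self, dc: int = 0, dh: int = 0, do: int = 0, dn: int = 0,
              ds: int = 0, dp: int = 0) -> "MolecularFormula":
        """Return a new formula displaced by the given element deltas.

        Used to walk homologous series, e.g. ``shift(dc=1, dh=2)`` adds one
        CH2 unit and ``shift(dc=4, dh=2)`` adds one C4H2 unit.
        """
        return replace(
            self,
            c=self.c + dc,
            h=self.h + dh,
            o=self.o + do,
            n=self.n + dn,
            s=self.s + ds,
            p=self.p + dp,
        )

    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "MolecularFormula":
        """Parse a Hill-order (or any element-count) string like ``C6H12O6``."""
        counts = dict.fromkeys("chonsp", 0)
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula string {text!r}")
            pos = match.end()
            el, num = match.groups()
            if el not in _FIELD_BY_ELEMENT:
                raise ValueError(f"unsupported element {el!r} in {text!r}")
            counts[_FIELD_BY_ELEMENT[el]] += int(num) if num else 1
        if pos != len(text):
            raise ValueError(f"cannot parse formula string {text!r}")
        return cls(charge=charge, **counts)

    def __str__(self) -> str:
        return self.hill
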