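"""Per-formula DOM descriptors: NOSC, aromaticity index, Van Krevelen class.

Two typographic variants of each index are first-class citizens:

* ``nosc`` — the nominal oxidation state of carbon.  The default
  ``standard`` variant is the literature form
  ``4 - (4C + H - 3N - 2O + 5P - 2S - z)/C`` (z = charge, 0 for neutral
  formulas).  The ``as_printed`` variant,
  ``4 - (5C + H - 3N - 2O - 2S)/C``, reproduces a widespread typeset
  corruption of the same expression (it equals standard - 1 whenever
  P = 0 and z = 0) and is kept so results computed under either reading
  can be compared explicitly.
* ``aromaticity_index`` — the Koch–Dittmar aromaticity index
  ``AI = (1 + C - O - S - 0.5H) / (C - O - S - N - P)`` (``standard``),
  its oxygen-discounted ``modified`` form (0.5·O in numerator and
  denominator), and an ``as_printed`` variant equal to ``4 - standard``.
  A non-positive numerator or denominator floors the index at 0.

Van Krevelen classes are rectangular H/C x O/C windows loaded from an
editable YAML table shipped with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .formula import MolecularFormula

__all__ = [
    "nosc",
    "aromaticity_index",
    "VanKrevelenTable",
    "load_default_vk_table",
    "vk_class",
    "annotate_table",
]

logger = logging.getLogger(__name__)

NOSC_VARIANTS = ("standard", "as_printed")
AI_VARIANTS = ("standard", "modified", "as_printed")


def nosc(f: MolecularFormula, variant: str = "standard") -> float:
    """Nominal oxidation state of carbon for one formula."""
    if f.c < 1:
        raise ValueError("NOSC requires at least one carbon")
    if variant == "standard":
        num = 4 * f.c + f.h - 3 * f.n - 2 * f.o + 5 * f.p - 2 * f.s - f.charge
    elif variant == "as_printed":
        num = 5 * f.c + f.h - 3 * f.n - 2 * f.o - 2 * f.s
    else:
        raise ValueError(f"unknown NOSC variant {variant!r}; use {NOSC_VARIANTS}")
    return 4 - num / f.c


def aromaticity_index(f: MolecularFormula, variant: str = "standard") -> float:
    """Aromaticity index; degenerate numerators/denominators floor to 0."""
    if variant == "as_printed":
        return 4 - aromaticity_index(f, "standard")
    if variant == "standard":
        num = 1 + f.c - f.o - f.s - 0.5 * f.h
        den = f.c - f.o - f.s - f.n - f.p
    elif variant == "modified":
        num = 1 + f.c - 0.5 * f.o - f.s - 0.5 * f.h
        den = f.c - 0.5 * f.o - f.s - f.n - f.p
    else:
        raise ValueError(f"unknown AI variant {variant!r}; use {AI_VARIANTS}")
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


@dataclass(frozen=True)
class VanKrevelenTable:
    """Half-open H/C x O/C rectangles labelling compound classes."""

    rects: tuple[tuple[str, float, float, float, float], ...]
    fallback: str = "other"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VanKrevelenTable":
        spec = yaml.safe_load(Path(path).read_text())
        rects = tuple(
            (r["name"], float(r["hc"][0]), float(r["hc"][1]),
             float(r["oc"][0]), float(r["oc"][1]))
            for r in spec["classes"]
        )
        return cls(rects=rects)

    def classify(self, hc: float, oc: float) -> str:
        for name, hlo, hhi, olo, ohi in self.rects:
            if hlo <= hc < hhi and olo <= oc < ohi:
                return name
        return self.fallback

    @property
    def class_names(self) -> list[str]:
        return [r[0] for r in self.rects] + [self.fallback]


_default_table: VanKrevelenTable | None = None


def load_default_vk_table() -> VanKrevelenTable:
    global _default_table
    if _default_table is None:
        with resources.as_file(
            resources.files("pyrodom") / "data" / "vk_classes.yaml"
        ) as p:
            _default_table = VanKrevelenTable.from_yaml(p)
    return _default_table


def vk_class(f: MolecularFormula, table: VanKrevelenTable | None = None) -> str:
    """Van Krevelen compound class of one formula (rectangle lookup)."""
    table = table or load_default_vk_table()
    return table.classify(f.hc, f.oc)


def annotate_table(
    aft,
    vk_table: VanKrevelenTable | None = None,
) -> pd.DataFrame:
    """Join per-formula descriptors onto an assigned-formula table.

    One metrics row per assigned cluster; unassigned clusters pass through
    with NA metrics.  Columns: hc, oc, nosc_standard, nosc_as_printed,
    ai_standard, ai_modified, ai_as_printed, vk_class.
    """
    vk_table = vk_table or load_default_vk_table()
    df = aft.table if hasattr(aft, "table") else aft
    if df["formula"].notna().sum() == 0:
        raise ValueError("assigned table has no assigned rows to annotate")
    cols = {k: [] for k in (
        "hc", "oc", "nosc_standard", "nosc_as_printed",
        "ai_standard", "ai_modified", "ai_as_printed", "vk_class",
    )}
    for hill in df["formula"]:
        if pd.isna(hill):
            for v in cols.values():
                v.append(pd.NA)
            continue
        f = MolecularFormula.from_string(hill)
        cols["hc"].append(f.hc)
        cols["oc"].append(f.oc)
        cols["nosc_standard"].append(nosc(f, "standard"))
        cols["nosc_as_printed"].append(nosc(f, "as_printed"))
        cols["ai_standard"].append(aromaticity_index(f, "standard"))
        cols["ai_modified"].append(aromaticity_index(f, "modified"))
        cols["ai_as_printed"].append(aromaticity_index(f, "as_printed"))
        cols["vk_class"].append(vk_table.classify(f.hc, f.oc))
    out = df.copy()
    for k, v in cols.items():
        out[k] = v
    return out
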