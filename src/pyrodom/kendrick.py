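"""Kendrick mass defect (KMD) analysis with the C4H2 base unit.

Rescaling masses so that one C4H2 unit (benzene addition to a growing
polyaromatic core) has integer mass makes all members of a C4H2
homologous series share a mass defect: ``KM = M * 50 / base_exact``,
``KMD = NKM - KM``.  Series are groups of >= 2 formulas with the same KMD
(within a tolerance) whose nominal Kendrick masses differ by multiples of
the 50-amu base unit, optionally retained only when their members appear
across a required set of burn-severity conditions.

Two NKM conventions are provided.  ``"mass"`` (default) rounds the
original mass M to the nearest integer.  ``"kendrick"`` rounds KM instead;
only under this convention is KMD *exactly* invariant under the addition
of k C4H2 units (rounding M can cross a half-integer boundary because the
exact unit mass exceeds 50 by 0.0157 Da).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import C4H2_MASS_EXACT, C4H2_NOMINAL

__all__ = [
    "KendrickConfig",
    "KendrickSeries",
    "kendrick_transform",
    "detect_series",
    "annotate_series_conditions",
    "filter_series_by_conditions",
    "series_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KendrickConfig:
    """Base unit, tolerances and retention rule for KMD analysis.

    ``base_exact`` defaults to the chemical monoisotopic mass of C4H2
    (50.01565); the value printed alongside the 50-amu nominal mass in
    parts of the pyrogenic-DOM literature (50.0587,
    ``constants.C4H2_MASS_PRINTED``) can be substituted, but it does not
    keep KMD constant along true C4H2 series.  ``mass_mode`` selects
    whether the transform runs on ion m/z (the measured quantity) or
    neutral masses.
    """

    base_nominal: float = C4H2_NOMINAL
    base_exact: float = C4H2_MASS_EXACT
    kmd_tolerance: float = 0.001
    step: int = 50
    require_conditions: frozenset[str] = frozenset(
        {"control", "low", "moderate", "high"}
    )
    nkm_convention: str = "mass"  # "mass" | "kendrick"
    mass_mode: str = "ion"  # "ion" | "neutral"

    def __post_init__(self) -> None:
        if self.base_exact <= 0 or self.base_nominal <= 0:
            raise ValueError("base masses must be positive")
        if self.kmd_tolerance < 0:
            raise ValueError("kmd_tolerance must be >= 0")
        if self.nkm_convention not in ("mass", "kendrick"):
            raise ValueError("nkm_convention must be 'mass' or 'kendrick'")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def kendrick_transform(
    masses: Sequence[float],
    cfg: KendrickConfig | None = None,
    formulas: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Kendrick records for a list of masses.

    Returns a frame with columns ``M``, ``KM``, ``NKM``, ``KMD`` (and
    ``formula`` when supplied):  ``KM = M * base_nominal / base_exact``,
    ``NKM`` = the configured rounding of M (or KM), ``KMD = NKM - KM``.
    """
    cfg = cfg or KendrickConfig()
    m = np.asarray(masses, dtype=float)
    if len(m) == 0:
        raise ValueError("masses must be non-empty")
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    km = m * cfg.base_nominal / cfg.base_exact
    nkm = _round_half_away(m if cfg.nkm_convention == "mass" else km)
    out = pd.DataFrame({"M": m, "KM": km, "NKM": nkm.astype(int), "KMD": nkm - km})
    if formulas is not None:
        out["formula"] = list(formulas)
    return out


@dataclass(frozen=True)
class KendrickSeries:
    """One homologous series: same KMD, NKMs spaced by the base unit."""

    series_id: int
    kmd_key: float
    nkms: tuple[int, ...]
    formulas: tuple[str, ...] = ()
    conditions_present: frozenset[str] = frozenset()
    retained: bool | None = None

    @property
    def n_members(self) -> int:
        return len(self.nkms)


def _split_by_tolerance(kmds: np.ndarray, idx: np.ndarray, tol: float):
    """Greedy grouping on sorted KMD, recursively split at the largest gap
    until every member lies within ``tol`` of the group mean."""
    groups = []
    start = 0
    run_sum = 0.0
    for i in range(len(idx)):
        n = i - start
        if n > 0 and kmds[i] - run_sum / n > tol:
            groups.append((start, i))
            start, run_sum = i, 0.0
        run_sum += kmds[i]
    groups.append((start, len(idx)))

    final = []
    stack = list(groups)
    while stack:
        a, b = stack.pop()
        seg = kmds[a:b]
        if len(seg) and np.max(np.abs(seg - seg.mean())) > tol and len(seg) > 1:
            gap = int(np.argmax(np.diff(seg))) + 1
            stack.append((a, a + gap))
            stack.append((a + gap, b))
        else:
            final.append((a, b))
    return sorted(final)


def detect_series(
    records: pd.DataFrame, cfg: KendrickConfig | None = None
) -> list[KendrickSeries]:
    """Group Kendrick records into homologous series.

    Records are sorted by KMD and grouped greedily within
    ``kmd_tolerance`` of the running group mean (with recursive splitting
    at the largest gap if the tolerance invariant is violated); each KMD
    group is then split by NKM residue class modulo the base step, and
    groups with >= 2 members become series.  Output order is
    deterministic: by kmd_key, then smallest member NKM.
    """
    cfg = cfg or KendrickConfig()
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    order = np.argsort(records["KMD"].to_numpy(), kind="stable")
    kmds = records["KMD"].to_numpy()[order]
    nkms = records["NKM"].to_numpy()[order]
    hills = (
        records["formula"].to_numpy()[order]
        if "formula" in records
        else np.array([""] * len(records), dtype=object)
    )

    raw = []
    for a, b in _split_by_tolerance(kmds, order, cfg.kmd_tolerance):
        residues: dict[int, list[int]] = {}
        for j in range(a, b):
            residues.setdefault(int(nkms[j]) % cfg.step, []).append(j)
        for members in residues.values():
            if len(members) >= 2:
                members = sorted(members, key=lambda j: (nkms[j], hills[j]))
                raw.append(
                    (
                        float(np.mean(kmds[members])),
                        tuple(int(nkms[j]) for j in members),
                        tuple(str(hills[j]) for j in members),
                    )
                )
    raw.sort(key=lambda t: (t[0], t[1][0]))
    series = [
        KendrickSeries(series_id=i, kmd_key=k, nkms=nk, formulas=fs)
        for i, (k, nk, fs) in enumerate(raw)
    ]
    logger.info("detected %d Kendrick series from %d records", len(series), len(records))
    return series


def annotate_series_conditions(
    series: Iterable[KendrickSeries],
    occupancy: Mapping[str, set[str]],
    cfg: KendrickConfig | None = None,
    member_mode: str = "union",
) -> list[KendrickSeries]:
    """Populate ``conditions_present`` and the retention flag per series.

    ``occupancy`` maps formula (Hill string) -> set of conditions in which
    it was detected.  ``member_mode="union"`` counts a series as present
    in a condition when ANY member is (default); ``"every"`` requires ALL
    members.  A series is retained when its presence set covers
    ``cfg.require_conditions``.
    """
    cfg = cfg or KendrickConfig()
    if member_mode not in ("union", "every"):
        raise ValueError("member_mode must be 'union' or 'every'")
    out = []
    for s in series:
        sets = [set(occupancy.get(f, set())) for f in s.formulas]
        if not sets:
            present: set[str] = set()
        elif member_mode == "union":
            present = set().union(*sets)
        else:
            present = set.intersection(*sets)
        retained = cfg.require_conditions <= present
        out.append(
            replace(s, conditions_present=frozenset(present), retained=retained)
        )
    return out


def filter_series_by_conditions(
    series: Iterable[KendrickSeries],
    occupancy: Mapping[str, set[str]],
    cfg: KendrickConfig | None = None,
    member_mode: str = "union",
) -> list[KendrickSeries]:
    """Series present across every required condition (see
    :func:`annotate_series_conditions`); an empty requirement retains all."""
    annotated = annotate_series_conditions(series, occupancy, cfg, member_mode)
    return [s for s in annotated if s.retained]


def series_frame(series: Iterable[KendrickSeries]) -> pd.DataFrame:
    """Flat CSV-ready view of a series list."""
    return pd.DataFrame(
        {
            "series_id": s.series_id,
            "kmd_key": s.kmd_key,
            "n_members": s.n_members,
            "nkms": ";".join(map(str, s.nkms)),
            "formulas": ";".join(s.formulas),
            "conditions_present": ";".join(sorted(s.conditions_present)),
            "retained": s.retained,
        }
        for s in series
    )
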