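"""CHONSP molecular-formula assignment by bounded exhaustive enumeration.

Each aligned consensus m/z is converted to a neutral mass (deprotonation
convention, negative mode) and every formula inside the configured element
bounds whose mass lies strictly within the ppm tolerance — and which passes
the chemical validity rules (H/C and O/C windows, RDBE >= 0 with integer
parity for even-electron neutrals) — is enumerated.  Candidates are ranked
by absolute mass error, then by heteroatom count (N+S+P), then by Hill
string, so assignment is fully deterministic.

The enumerator loops over the heteroatom/oxygen grid and solves for the
(C, H) pair by residual-mass bounding: for a fixed (N, S, P, O) block and
carbon count, at most one hydrogen count can land within a sub-ppm window
(the H mass far exceeds twice the tolerance), so the search is exhaustive
without iterating hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import ELEMENT_MASS, PROTON_MASS
from .formula import MolecularFormula

__all__ = [
    "AssignmentConfig",
    "AssignedFormulaTable",
    "neutral_mass",
    "enumerate_candidates",
    "assign_table",
]

logger = logging.getLogger(__name__)

#: Conventional DOM element bounds (the element SET is fixed by the method;
#: the windows are configurable).
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (1, 100),
    "H": (1, 200),
    "O": (0, 60),
    "N": (0, 5),
    "S": (0, 2),
    "P": (0, 2),
}


@dataclass(frozen=True)
class AssignmentConfig:
    """Tolerance, element bounds and validity rules for formula assignment.

    ``tol_ppm`` is a strict bound: a candidate is kept only when
    ``|error_ppm| < tol_ppm``.  ``hc_range`` / ``oc_range`` are closed
    intervals on the atomic ratios.  With
    ``require_integer_rdbe_parity=True`` the ring-and-double-bond
    equivalent must be a non-negative integer, the even-electron condition
    for a neutral CHONSP molecule.
    """

    tol_ppm: float = 0.5
    bounds: tuple[tuple[str, tuple[int, int]], ...] = tuple(DEFAULT_BOUNDS.items())
    hc_range: tuple[float, float] = (0.2, 3.0)
    oc_range: tuple[float, float] = (0.0, 1.5)
    require_integer_rdbe_parity: bool = True
    #: strict mode: reject a cluster when the top two candidates are closer
    #: than this many ppm apart (near-degenerate assignment).
    strict_margin_ppm: float = 0.05

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        for el, (lo, hi) in self.bounds:
            if lo > hi or lo < 0:
                raise ValueError(f"invalid bounds for element {el}: ({lo}, {hi})")

    @property
    def bounds_dict(self) -> dict[str, tuple[int, int]]:
        return dict(self.bounds)

    def is_valid_formula(self, f: MolecularFormula) -> bool:
        """Apply element bounds and chemical validity rules to one formula."""
        b = self.bounds_dict
        for el, attr in (("C", "c"), ("H", "h"), ("O", "o"), ("N", "n"),
                         ("S", "s"), ("P", "p")):
            lo, hi = b[el]
            if not lo <= getattr(f, attr) <= hi:
                return False
        if not self.hc_range[0] <= f.hc <= self.hc_range[1]:
            return False
        if not self.oc_range[0] <= f.oc <= self.oc_range[1]:
            return False
        if f.rdbe < 0:
            return False
        if self.require_integer_rdbe_parity and (f.h - f.n - f.p) % 2 != 0:
            return False
        return True


def neutral_mass(mz: float, z: int = -1) -> float:
    """Neutral monoisotopic mass of a singly deprotonated ion.

    Only ``z = -1`` ([M-H]-, negative electrospray) is supported; the
    neutral mass is ``m/z + 1.00727646``.
    """
    if z != -1:
        raise ValueError(
            f"unsupported charge state z={z}; only z=-1 ([M-H]-) is supported"
        )
    return mz + PROTON_MASS


@lru_cache(maxsize=8)
def _hetero_grid(bounds: tuple[tuple[str, tuple[int, int]], ...]):
    """Flattened (N, S, P, O) grid and base masses for an element-bounds key."""
    b = dict(bounds)
    n = np.arange(b["N"][0], b["N"][1] + 1)
    s = np.arange(b["S"][0], b["S"][1] + 1)
    p = np.arange(b["P"][0], b["P"][1] + 1)
    o = np.arange(b["O"][0], b["O"][1] + 1)
    N, S, P, O = (a.ravel() for a in np.meshgrid(n, s, p, o, indexing="ij"))
    base = (
        N * ELEMENT_MASS["N"]
        + S * ELEMENT_MASS["S"]
        + P * ELEMENT_MASS["P"]
        + O * ELEMENT_MASS["O"]
    )
    c = np.arange(b["C"][0], b["C"][1] + 1)
    return N, S, P, O, base, c


def enumerate_candidates(
    mass: float, cfg: AssignmentConfig | None = None
) -> list[tuple[MolecularFormula, float]]:
    """All formulas within ``cfg`` bounds matching ``mass`` under the tolerance.

    Returns ``(formula, error_ppm)`` pairs with
    ``error_ppm = (formula.mass - mass) / mass * 1e6``, sorted by
    ``|error_ppm|``, then heteroatom count N+S+P, then Hill string.  An
    empty list means no assignment is possible.
    """
    cfg = cfg or AssignmentConfig()
    if mass <= 0:
        raise ValueError("mass must be positive")
    N, S, P, O, base, c = _hetero_grid(cfg.bounds)
    mh = ELEMENT_MASS["H"]

    # restrict the carbon axis to masses that can still fit
    c = c[c * 12.0 <= mass + 1.0]
    if len(c) == 0:
        return []

    # residual mass left for C and H, per (hetero combo, carbon count); at
    # a sub-ppm tolerance only the nearest integer hydrogen count can match
    rem = (mass - base)[:, None] - 12.0 * c[None, :]
    h = np.rint(rem / mh)
    err_da = rem - h * mh  # mass - candidate_mass
    tol_da = cfg.tol_ppm * 1e-6 * mass

    gi, ci = np.nonzero(np.abs(err_da) < tol_da)
    out: list[tuple[MolecularFormula, float]] = []
    for g, j in zip(gi, ci):
        hij = int(h[g, j])
        if hij < 0:
            continue
        f = MolecularFormula(
            c=int(c[j]), h=hij, o=int(O[g]),
            n=int(N[g]), s=int(S[g]), p=int(P[g]),
        )
        if cfg.is_valid_formula(f):
            out.append((f, (f.mass - mass) / mass * 1e6))
    out.sort(key=lambda t: (abs(t[1]), t[0].n + t[0].s + t[0].p, t[0].hill))
    return out


@dataclass
class AssignedFormulaTable:
    """Per-cluster formula assignments joined to per-sample intensities.

    ``table`` carries one row per aligned cluster: ``cluster_id``,
    ``consensus_mz``, ``neutral_mass``, ``formula`` (Hill string or NA),
    ``error_ppm``, ``n_candidates``, ``reason`` (NA when assigned,
    otherwise ``no_candidate`` / ``ambiguous_if_strict``), followed by one
    intensity column per sample (NaN where the sample had no peak).
    """

    table: pd.DataFrame
    sample_columns: list[str] = field(default_factory=list)

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["formula"].notna()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8f")


def assign_table(
    apt, cfg: AssignmentConfig | None = None, strict: bool = False
) -> AssignedFormulaTable:
    """Assign a formula (or a reason code) to every aligned cluster.

    Each cluster's consensus m/z is neutralized and the top-ranked
    candidate within tolerance is taken.  In strict mode a cluster whose
    top two candidates differ by less than ``cfg.strict_margin_ppm`` in
    absolute error is left unassigned with reason ``ambiguous_if_strict``.
    """
    cfg = cfg or AssignmentConfig()
    consensus = apt.consensus_mz
    if len(consensus) == 0:
        raise ValueError("aligned table is empty")
    rows = []
    for cid, mz in consensus.items():
        nm = neutral_mass(float(mz))
        cands = enumerate_candidates(nm, cfg)
        rec = {
            "cluster_id": cid,
            "consensus_mz": float(mz),
            "neutral_mass": nm,
            "formula": pd.NA,
            "error_ppm": np.nan,
            "n_candidates": len(cands),
            "reason": pd.NA,
        }
        if not cands:
            rec["reason"] = "no_candidate"
        elif (
            strict
            and len(cands) > 1
            and abs(cands[1][1]) - abs(cands[0][1]) < cfg.strict_margin_ppm
        ):
            rec["reason"] = "ambiguous_if_strict"
        else:
            f, err = cands[0]
            rec["formula"] = f.hill
            rec["error_ppm"] = err
        rows.append(rec)
    out = pd.DataFrame(rows)
    samples = list(apt.intensities.columns)
    out = out.merge(
        apt.intensities, left_on="cluster_id", right_index=True, how="left"
    )
    n_assigned = int(out["formula"].notna().sum())
    logger.info("assigned %d / %d clusters", n_assigned, len(out))
    return AssignedFormulaTable(table=out, sample_columns=samples)


def ambiguity_by_mass_bin(
    masses: Iterable[float], cfg: AssignmentConfig | None = None, bin_da: float = 100.0
) -> pd.DataFrame:
    """Fraction of masses with more than one candidate, per mass bin.

    Assignment ambiguity grows with mass as the density of valid CHONSP
    formulas increases; this reports the rate per ``bin_da`` Da bin.
    """
    cfg = cfg or AssignmentConfig()
    recs = []
    for m in masses:
        n = len(enumerate_candidates(m, cfg))
        recs.append((np.floor(m / bin_da) * bin_da, n))
    df = pd.DataFrame(recs, columns=["bin_lo", "n_candidates"])
    grp = df.groupby("bin_lo")["n_candidates"]
    return pd.DataFrame(
        {
            "n_masses": grp.size(),
            "ambiguous_fraction": grp.apply(lambda s: float((s > 1).mean())),
            "mean_candidates": grp.mean(),
        }
    ).reset_index()
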