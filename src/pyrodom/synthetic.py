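"""Seeded synthetic DOM spectra with planted burn-severity effects.

The generator emulates negative-mode, singly charged ([M-H]-) FTICR-MS
peak lists of water-extractable soil organic matter across a burn-severity
gradient.  Each condition's formula pool is a shared core plus a
condition-unique stratum; an "aromatic" stratum (aromaticity index
>= 0.5, low H/C) is planted with a condition-dependent fraction so that
higher severities carry more condensed, fire-derived formulas.  Formulas
are drawn as homologous families — CH2 ladders in the aliphatic stratum,
C4H2 (benzene-addition) ladders in the aromatic stratum — because natural
DOM is series-rich and the downstream recalibration and Kendrick stages
key on exactly those series.

Observed m/z values carry sub-ppm Gaussian error plus an optional
systematic calibration drift (constant, or linear in m/z); intensities are
log-normal; when enabled, each detected formula also emits a single-13C
isotopologue satellite at +1.0033548 Da with intensity 0.011 x C x parent
(the leading binomial term of natural 13C abundance).  Every output is a
pure function of the design and its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .assign import AssignmentConfig
from .constants import C13_C12_DELTA, PROTON_MASS
from .formula import MolecularFormula
from .metrics import aromaticity_index
from .peaks import PeakList

__all__ = [
    "SyntheticDesign",
    "generate_formula_pool",
    "synthesize_peaklists",
    "sample_detection",
    "design_metadata",
    "write_dataset",
]

logger = logging.getLogger(__name__)

_POOL_STREAM, _PEAKS_STREAM = 0, 1

#: Replication mirroring the surface-soil comparison this generator emulates
#: (4 control, 6 low, 5 moderate, 6 high severity samples).
DEFAULT_REPLICATES: dict[str, int] = {"control": 4, "low": 6, "moderate": 5, "high": 6}

DEFAULT_AROMATIC_FRACTIONS: dict[str, float] = {
    "control": 0.05, "low": 0.15, "moderate": 0.25, "high": 0.40,
}


def _default_conditions() -> tuple[str, ...]:
    return ("control", "low", "moderate", "high")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design of one synthetic dataset.

    Notes
    -----
    * ``replicates_per_condition`` may be a single integer or a mapping
      condition -> count; the default mirrors a replicated surface-soil
      severity gradient (4/6/5/6).
    * ``aromatic_fraction_by_condition`` plants the severity effect: the
      shared core carries the minimum fraction of aromatic (AI >= 0.5)
      formulas, and each condition's unique stratum is drawn with its own
      condition's fraction, so the realized pool fraction is
      ``(min_f * n_core + f_c * n_unique) / (n_core + n_unique)`` —
      strictly increasing in ``f_c``.
    * ``calibration_drift_ppm`` is either a constant ppm offset or an
      ``(a, b)`` pair giving ``a + b * mz`` ppm.
    * Identical seed + design => byte-identical output files.
    """

    conditions: tuple[str, ...] = field(default_factory=_default_conditions)
    replicates_per_condition: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    n_core_formulas: int = 2000
    n_unique_formulas_per_condition: int = 150
    aromatic_fraction_by_condition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AROMATIC_FRACTIONS)
    )
    mass_error_sd_ppm: float = 0.1
    calibration_drift_ppm: float | tuple[float, float] = 0.0
    detection_prob: float = 0.9
    intensity_lognormal_params: tuple[float, float] = (13.0, 1.0)
    isotopologue_enabled: bool = True
    depth: str = "surface"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.n_core_formulas < 1:
            raise ValueError("n_core_formulas must be positive")
        if self.n_unique_formulas_per_condition < 0:
            raise ValueError("n_unique_formulas_per_condition must be non-negative")
        for cond in self.conditions:
            f = self.aromatic_fraction_by_condition.get(cond)
            if f is None or not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"aromatic_fraction_by_condition[{cond!r}] must be in [0, 1]"
                )
            if self.replicates(cond) < 1:
                raise ValueError(f"replicates_per_condition[{cond!r}] must be >= 1")
        if self.mass_error_sd_ppm < 0:
            raise ValueError("mass_error_sd_ppm must be >= 0")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in (0, 1]")

    def replicates(self, condition: str) -> int:
        if isinstance(self.replicates_per_condition, int):
            return self.replicates_per_condition
        return int(self.replicates_per_condition.get(condition, 0))

    def drift_ppm(self, mz):
        if isinstance(self.calibration_drift_ppm, (int, float)):
            return np.full_like(np.asarray(mz, dtype=float), float(self.calibration_drift_ppm))
        a, b = self.calibration_drift_ppm
        return a + b * np.asarray(mz, dtype=float)


def _rng(design: SyntheticDesign, stream: int) -> np.random.Generator:
    """Stage-scoped RNG: SeedSequence([seed, stream]) keeps stages independent."""
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


# --- formula sampling -------------------------------------------------------

_MASS_LO, _MASS_HI = 205.0, 895.0
_VALIDITY = AssignmentConfig()


def _stratum_ok(f: MolecularFormula, aromatic: bool) -> bool:
    ai = aromaticity_index(f, "standard")
    return ai >= 0.5 if aromatic else ai < 0.5


def _valid(f: MolecularFormula, aromatic: bool) -> bool:
    return (
        _MASS_LO <= f.mass <= _MASS_HI
        and _VALIDITY.is_valid_formula(f)
        and _stratum_ok(f, aromatic)
    )


def _sample_base(rng: np.random.Generator, aromatic: bool) -> MolecularFormula:
    for _ in range(500):
        c = int(rng.integers(10, 42))
        if aromatic:
            hc = rng.uniform(0.25, 0.85)
            oc = rng.uniform(0.02, 0.45)
        else:
            hc = rng.uniform(0.95, 2.1)
            oc = rng.uniform(0.1, 0.9)
        h = max(1, round(c * hc))
        o = round(c * oc)
        n = int(rng.choice([0, 0, 0, 0, 1, 2]))
        s = int(rng.choice([0] * 9 + [1]))
        p = int(rng.choice([0] * 9 + [1]))
        if (h - n - p) % 2:  # integer-RDBE parity for even-electron neutrals
            h += 1
        try:
            f = MolecularFormula(c=c, h=h, o=o, n=n, s=s, p=p)
        except ValueError:
            continue
        if _valid(f, aromatic):
            return f
    raise RuntimeError("formula rejection sampling failed (500 attempts)")


def _sample_family(
    rng: np.random.Generator, aromatic: bool, used: set[MolecularFormula]
) -> list[MolecularFormula]:
    """One homologous family: C4H2 ladder if aromatic, else CH2 ladder."""
    base = _sample_base(rng, aromatic)
    dc, dh = (4, 2) if aromatic else (1, 2)
    length = int(rng.integers(2, 7))
    fam: list[MolecularFormula] = []
    f = base
    for _ in range(length):
        if not _valid(f, aromatic) or f in used:
            break
        fam.append(f)
        used.add(f)
        f = f.shift(dc=dc, dh=dh)
    return fam


def _sample_stratified(
    rng: np.random.Generator,
    n_total: int,
    n_aromatic: int,
    used: set[MolecularFormula],
) -> list[MolecularFormula]:
    out: list[MolecularFormula] = []
    for aromatic, target in ((True, n_aromatic), (False, n_total - n_aromatic)):
        got: list[MolecularFormula] = []
        while len(got) < target:
            got.extend(_sample_family(rng, aromatic, used))
        out.extend(got[:target])
        for extra in got[target:]:  # trimmed members stay available elsewhere
            used.discard(extra)
    return out


def generate_formula_pool(
    design: SyntheticDesign,
) -> dict[str, set[MolecularFormula]]:
    """Per-condition formula pools: shared core + condition-unique strata.

    All formulas pass the default assignment validity rules, have neutral
    masses inside the generator window, and the aromatic stratum satisfies
    AI >= 0.5 (standard variant).  With
    ``n_unique_formulas_per_condition = 0`` every condition receives an
    identical pool.
    """
    rng = _rng(design, _POOL_STREAM)
    fractions = {c: design.aromatic_fraction_by_condition[c] for c in design.conditions}
    f_min = min(fractions.values())

    used: set[MolecularFormula] = set()
    n_arom_core = round(f_min * design.n_core_formulas)
    core = _sample_stratified(rng, design.n_core_formulas, n_arom_core, used)

    pools: dict[str, set[MolecularFormula]] = {}
    for cond in design.conditions:
        n_uni = design.n_unique_formulas_per_condition
        if n_uni == 0:
            pools[cond] = set(core)
            continue
        n_arom_uni = round(fractions[cond] * n_uni)
        uniq = _sample_stratified(rng, n_uni, n_arom_uni, used)
        pools[cond] = set(core) | set(uniq)
    return pools


def sample_detection(
    formulas: list[MolecularFormula],
    design: SyntheticDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli detection mask for one replicate (one draw per formula)."""
    return rng.random(len(formulas)) < design.detection_prob


def design_metadata(design: SyntheticDesign) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{cond}_{r:02d}",
            "condition": cond,
            "depth": design.depth,
            "replicate": r,
        }
        for cond in design.conditions
        for r in range(1, design.replicates(cond) + 1)
    ]
    return pd.DataFrame(rows)


def synthesize_peaklists(
    pools: Mapping[str, set[MolecularFormula]],
    design: SyntheticDesign,
) -> tuple[list[PeakList], pd.DataFrame]:
    """Per-replicate peak lists plus the ground-truth peak -> formula map.

    Each pool formula appears in a replicate with probability
    ``detection_prob``; its observed m/z is
    ``(mass - proton) * (1 + eps*1e-6)`` with ``eps ~ Normal(drift, sd)``
    in ppm.  The ground-truth frame has one row per emitted peak
    (``sample_id``, ``mz``, ``formula``, ``is_isotopologue``) and covers
    every monoisotopic peak exactly once.
    """
    if not pools or any(len(v) == 0 for v in pools.values()):
        raise ValueError("pools must be non-empty for every condition")
    rng = _rng(design, _PEAKS_STREAM)
    mu, sigma = design.intensity_lognormal_params
    peaklists: list[PeakList] = []
    gt_rows: list[pd.DataFrame] = []
    for cond in design.conditions:
        formulas = sorted(pools[cond], key=lambda f: (f.mass, f.hill))
        masses = np.array([f.mass for f in formulas])
        carbons = np.array([f.c for f in formulas])
        hills = np.array([f.hill for f in formulas], dtype=object)
        ion_true = masses - PROTON_MASS
        for r in range(1, design.replicates(cond) + 1):
            sample_id = f"{cond}_{r:02d}"
            det = sample_detection(formulas, design, rng)
            eps = rng.normal(design.drift_ppm(ion_true), design.mass_error_sd_ppm)
            inten = rng.lognormal(mu, sigma, size=len(formulas))
            mz = ion_true[det] * (1 + eps[det] * 1e-6)
            frames = [
                pd.DataFrame(
                    {
                        "mz": mz,
                        "intensity": inten[det],
                        "formula": hills[det],
                        "is_isotopologue": False,
                    }
                )
            ]
            if design.isotopologue_enabled:
                sat_true = ion_true[det] + C13_C12_DELTA
                sat_mz = sat_true * (1 + eps[det] * 1e-6)
                frames.append(
                    pd.DataFrame(
                        {
                            "mz": sat_mz,
                            "intensity": 0.011 * carbons[det] * inten[det],
                            "formula": hills[det],
                            "is_isotopologue": True,
                        }
                    )
                )
            allp = pd.concat(frames, ignore_index=True).sort_values(
                "mz", kind="mergesort"
            ).reset_index(drop=True)
            peaklists.append(
                PeakList(
                    sample_id=sample_id,
                    peaks=allp[["mz", "intensity"]],
                    condition=cond,
                    depth=design.depth,
                )
            )
            gt_rows.append(allp.assign(sample_id=sample_id))
    ground_truth = pd.concat(gt_rows, ignore_index=True)[
        ["sample_id", "mz", "formula", "is_isotopologue"]
    ]
    logger.info(
        "synthesized %d samples, %d peaks total", len(peaklists), len(ground_truth)
    )
    return peaklists, ground_truth


def write_dataset(
    peaklists: list[PeakList],
    ground_truth: pd.DataFrame,
    metadata: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, str]:
    """Write per-sample peak CSVs, metadata.csv and ground_truth.csv.

    Float formatting is fixed so identical designs/seeds produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pl in peaklists:
        p = outdir / f"{pl.sample_id}.csv"
        pl.peaks.to_csv(p, index=False, float_format="%.8f")
        paths[pl.sample_id] = str(p)
    metadata.to_csv(outdir / "metadata.csv", index=False)
    ground_truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.8f")
    paths["metadata"] = str(outdir / "metadata.csv")
    paths["ground_truth"] = str(outdir / "ground_truth.csv")
    return paths
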