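"""Peak-list filtering, internal recalibration and cross-sample alignment.

The pipeline starts from centroided peak lists (one per sample).  Peaks
outside the analysis m/z window are dropped, less-abundant 13C
isotopologue satellites are removed, each sample is internally
recalibrated against confidently assignable CH2 homologous series, and the
recalibrated lists are aligned across samples into consensus clusters at a
ppm tolerance.  Every operation returns both the surviving peaks and a log
of what was removed, so peak accounting is conserved end to end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .assign import AssignmentConfig, enumerate_candidates, neutral_mass
from .constants import C13_C12_DELTA, PROTON_MASS

__all__ = [
    "PeakList",
    "FilterResult",
    "CalibrationModel",
    "RecalibrationResult",
    "AlignedPeakTable",
    "filter_mz_window",
    "remove_isotopologues",
    "recalibrate",
    "align_peaks",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakList:
    """Centroided peaks of one sample, sorted ascending by m/z.

    ``peaks`` has columns ``mz`` and ``intensity`` (both positive).
    """

    sample_id: str
    peaks: pd.DataFrame
    condition: str | None = None
    depth: str | None = None

    def __post_init__(self) -> None:
        df = self.peaks
        if not {"mz", "intensity"}.issubset(df.columns):
            raise ValueError("peaks frame needs 'mz' and 'intensity' columns")
        if len(df) and ((df["mz"] <= 0).any() or (df["intensity"] <= 0).any()):
            raise ValueError("mz and intensity must be strictly positive")
        self.peaks = df.sort_values("mz", kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: pd.DataFrame) -> "PeakList":
        return PeakList(self.sample_id, peaks, self.condition, self.depth)


class FilterResult(NamedTuple):
    """Kept peaks plus a log frame of the removed ones."""

    peaklist: PeakList
    removed: pd.DataFrame


def filter_mz_window(pl: PeakList, lo: float = 200.0, hi: float = 900.0) -> FilterResult:
    """Keep peaks with ``lo <= mz <= hi`` (closed interval).

    The removal log records each dropped peak with reason ``mz_window``.
    An empty result raises a warning, not an error.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    keep = (pl.peaks["mz"] >= lo) & (pl.peaks["mz"] <= hi)
    removed = pl.peaks[~keep].assign(reason="mz_window", sample_id=pl.sample_id)
    kept = pl.with_peaks(pl.peaks[keep])
    if len(kept) == 0:
        warnings.warn(f"sample {pl.sample_id}: no peaks left in [{lo}, {hi}]")
    return FilterResult(kept, removed.reset_index(drop=True))


def remove_isotopologues(
    pl: PeakList, spacing: float = C13_C12_DELTA, tol_ppm: float = 1.0
) -> FilterResult:
    """Drop peaks that have a more abundant isotopologue one 13C below.

    A peak P is removed iff some peak Q satisfies
    ``|mz_P - spacing - mz_Q| <= tol_ppm * mz_P * 1e-6`` with
    ``intensity_Q > intensity_P``.  Removal decisions are evaluated against
    the input list simultaneously, which makes the operation idempotent:
    survivors can only lose potential parents, never gain them.
    """
    mz = pl.peaks["mz"].to_numpy()
    inten = pl.peaks["intensity"].to_numpy()
    target = mz - spacing
    win = tol_ppm * mz * 1e-6
    lo = np.searchsorted(mz, target - win, side="left")
    hi = np.searchsorted(mz, target + win, side="right")
    drop = np.zeros(len(mz), dtype=bool)
    for i in range(len(mz)):
        if hi[i] > lo[i] and np.any(inten[lo[i]:hi[i]] > inten[i]):
            drop[i] = True
    removed = pl.peaks[drop].assign(reason="isotopologue", sample_id=pl.sample_id)
    return FilterResult(pl.with_peaks(pl.peaks[~drop]), removed.reset_index(drop=True))


@dataclass
class CalibrationModel:
    """Linear ppm error model ``ppm_error(mz) = a + b * mz``.

    ``correct`` inverts the model: ``mz_true ~ mz_obs / (1 + ppm(mz_obs)*1e-6)``.
    ``applied`` is False when too few anchors were found and the model is
    the identity.
    """

    a: float = 0.0
    b: float = 0.0
    n_anchors: int = 0
    residual_rms_ppm: float = float("nan")
    applied: bool = False

    def ppm(self, mz):
        return self.a + self.b * np.asarray(mz, dtype=float)

    def correct(self, mz):
        mz = np.asarray(mz, dtype=float)
        return mz / (1.0 + self.ppm(mz) * 1e-6)


class RecalibrationResult(NamedTuple):
    peaklist: PeakList
    model: CalibrationModel


def _detect_ch2_anchors(
    pl: PeakList,
    cfg: AssignmentConfig,
    max_anchor_peaks: int = 400,
    min_series_len: int = 3,
) -> list[tuple[float, float]]:
    """Auto-detect (observed m/z, theoretical m/z) anchor pairs.

    Anchors are peaks whose neutral mass has a unique candidate formula
    within the anchor tolerance AND whose formula belongs to a CH2
    homologous ladder (same O/N/S/P and constant h - 2c) with at least
    ``min_series_len`` members among the confidently assigned peaks.  Only
    the ``max_anchor_peaks`` most intense peaks are examined.
    """
    df = pl.peaks.nlargest(max_anchor_peaks, "intensity")
    unique: list[tuple[float, object]] = []
    for mz in df["mz"]:
        cands = enumerate_candidates(neutral_mass(float(mz)), cfg)
        if len(cands) == 1:
            unique.append((float(mz), cands[0][0]))
    ladders: dict[tuple, list[tuple[float, object]]] = {}
    for mz, f in unique:
        key = (f.o, f.n, f.s, f.p, f.h - 2 * f.c)
        ladders.setdefault(key, []).append((mz, f))
    anchors = []
    for members in ladders.values():
        if len({f.c for _, f in members}) >= min_series_len:
            for mz, f in members:
                anchors.append((mz, f.mass - PROTON_MASS))
    return sorted(anchors)


def recalibrate(
    pl: PeakList,
    anchor_series: Sequence[tuple[float, float]] | None = None,
    anchor_config: AssignmentConfig | None = None,
    min_anchors: int = 5,
    max_anchor_peaks: int = 400,
) -> RecalibrationResult:
    """Internally recalibrate one sample against homologous-series anchors.

    Fits ``ppm_error(mz) = a + b*mz`` by least squares over anchor pairs
    (observed m/z, theoretical m/z) and applies the inverse correction.
    When ``anchor_series`` is not supplied, anchors are auto-detected as
    uniquely assignable peaks forming CH2 ladders (see
    :func:`_detect_ch2_anchors`).  Fewer than ``min_anchors`` anchors
    yields an identity model and a warning; the peak list passes through
    unchanged.
    """
    if anchor_series is None:
        cfg = anchor_config or AssignmentConfig(tol_ppm=1.0)
        anchor_series = _detect_ch2_anchors(pl, cfg, max_anchor_peaks)
    anchors = list(anchor_series)
    if len(anchors) < min_anchors:
        warnings.warn(
            f"sample {pl.sample_id}: only {len(anchors)} anchors found "
            f"(need {min_anchors}); recalibration skipped"
        )
        return RecalibrationResult(pl, CalibrationModel(n_anchors=len(anchors)))
    obs = np.array([a[0] for a in anchors])
    true = np.array([a[1] for a in anchors])
    err = (obs - true) / true * 1e6
    b, a = np.polyfit(obs, err, 1)
    model = CalibrationModel(a=float(a), b=float(b), n_anchors=len(anchors), applied=True)
    resid = (model.correct(obs) - true) / true * 1e6
    model.residual_rms_ppm = float(np.sqrt(np.mean(resid**2)))
    corrected = pl.peaks.assign(mz=model.correct(pl.peaks["mz"].to_numpy()))
    logger.info(
        "sample %s: recalibrated with %d anchors (a=%.4f ppm, b=%.3e ppm/Th, "
        "residual RMS %.4f ppm)",
        pl.sample_id, model.n_anchors, model.a, model.b, model.residual_rms_ppm,
    )
    return RecalibrationResult(pl.with_peaks(corrected), model)


@dataclass
class AlignedPeakTable:
    """Cross-sample peak clusters at a ppm tolerance.

    ``consensus_mz`` is indexed by cluster_id; ``intensities`` is a
    cluster x sample frame (NaN = absent); ``members`` is the long-form
    membership table and ``unresolved`` logs within-sample duplicates that
    were displaced by a more intense peak from the same sample.
    """

    consensus_mz: pd.Series
    intensities: pd.DataFrame
    members: pd.DataFrame
    unresolved: pd.DataFrame
    tol_ppm: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        wide = self.intensities.copy()
        wide.insert(0, "consensus_mz", self.consensus_mz)
        wide.index.name = "cluster_id"
        return wide.reset_index()


def align_peaks(pls: Sequence[PeakList], tol_ppm: float = 0.5) -> AlignedPeakTable:
    """Greedy consensus clustering of all samples' peaks at ``tol_ppm``.

    All peaks are pooled and sorted ascending by m/z (ties broken by
    sample id, so the result is invariant to input sample order).  A new
    cluster starts whenever the next peak deviates from the running
    cluster consensus (unweighted mean m/z) by more than ``tol_ppm``.
    Within a cluster each sample contributes at most one peak — the most
    intense; displaced peaks are logged as unresolved.
    """
    if not pls:
        raise ValueError("need at least one peak list")
    frames = [
        pl.peaks.assign(sample_id=pl.sample_id)[["mz", "intensity", "sample_id"]]
        for pl in pls
    ]
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values(
        ["mz", "sample_id", "intensity"], kind="mergesort"
    ).reset_index(drop=True)

    mz = pool["mz"].to_numpy()
    labels = np.empty(len(pool), dtype=int)
    cid = -1
    csum = 0.0
    cn = 0
    for i in range(len(pool)):
        if cn == 0 or (mz[i] - csum / cn) / (csum / cn) * 1e6 > tol_ppm:
            cid += 1
            csum, cn = 0.0, 0
        labels[i] = cid
        csum += mz[i]
        cn += 1
    pool["cluster_id"] = labels

    # one peak per sample per cluster: keep the most intense, log the rest
    order = pool.sort_values(
        ["cluster_id", "sample_id", "intensity", "mz"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    dup = order.duplicated(["cluster_id", "sample_id"], keep="first")
    unresolved = order[dup].assign(reason="alignment_unresolved")
    members = order[~dup].sort_values(["cluster_id", "sample_id"], kind="mergesort")

    consensus = members.groupby("cluster_id")["mz"].mean().rename("consensus_mz")
    intensities = members.pivot(
        index="cluster_id", columns="sample_id", values="intensity"
    )
    # every sample gets a column even if it never contributed a peak
    all_samples = [pl.sample_id for pl in sorted(pls, key=lambda p: p.sample_id)]
    intensities = intensities.reindex(columns=all_samples)
    logger.info(
        "aligned %d peaks from %d samples into %d clusters (%d unresolved)",
        len(pool), len(pls), len(consensus), len(unresolved),
    )
    return AlignedPeakTable(
        consensus_mz=consensus,
        intensities=intensities,
        members=members.reset_index(drop=True),
        unresolved=unresolved.reset_index(drop=True),
        tol_ppm=tol_ppm,
    )
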