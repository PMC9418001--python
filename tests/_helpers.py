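"""Shared mini-pipeline helper for integration-style tests."""

from __future__ import annotations

import pandas as pd

from pyrodom.assign import AssignmentConfig, assign_table
from pyrodom.compare import build_presence
from pyrodom.metrics import annotate_table
from pyrodom.peaks import (
    AlignedPeakTable,
    align_peaks,
    filter_mz_window,
    recalibrate,
    remove_isotopologues,
)
from pyrodom.synthetic import (
    SyntheticDesign,
    design_metadata,
    generate_formula_pool,
    synthesize_peaklists,
)


def make_aligned(mzs, intensities=None, samples=("s1",)) -> AlignedPeakTable:
    """Minimal aligned table with one cluster per m/z, same across samples."""
    consensus = pd.Series(list(mzs), index=range(len(mzs)), name="consensus_mz")
    inten = pd.DataFrame(
        {s: intensities or [1.0] * len(mzs) for s in samples}, index=range(len(mzs))
    )
    return AlignedPeakTable(
        consensus_mz=consensus, intensities=inten,
        members=pd.DataFrame(), unresolved=pd.DataFrame(),
    )


def run_mini_pipeline(design: SyntheticDesign, do_recalibrate: bool = False,
                      cfg: AssignmentConfig | None = None):
    """Generator -> filter -> isotopologue removal -> (recal) -> align -> assign.

    Returns a dict with every intermediate needed by the tests.
    """
    pools = generate_formula_pool(design)
    peaklists, ground_truth = synthesize_peaklists(pools, design)
    cleaned = []
    for pl in peaklists:
        pl = filter_mz_window(pl).peaklist
        pl = remove_isotopologues(pl).peaklist
        if do_recalibrate:
            pl = recalibrate(pl).peaklist
        cleaned.append(pl)
    apt = align_peaks(cleaned)
    aft = assign_table(apt, cfg or AssignmentConfig())
    metadata = design_metadata(design)
    return {
        "pools": pools,
        "peaklists": peaklists,
        "ground_truth": ground_truth,
        "aligned": apt,
        "assigned": aft,
        "metadata": metadata,
        "presence": build_presence(aft, metadata),
        "metrics": annotate_table(aft),
    }


def truth_by_cluster(apt, ground_truth: pd.DataFrame, tol_ppm: float = 0.5):
    """Map cluster_id -> ground-truth formula via nearest monoisotopic peak."""
    gt = ground_truth[~ground_truth["is_isotopologue"]].sort_values("mz")
    mz = gt["mz"].to_numpy()
    hills = gt["formula"].to_numpy()
    import numpy as np

    out = {}
    for cid, cmz in apt.consensus_mz.items():
        i = np.searchsorted(mz, cmz)
        best, bestd = None, None
        for j in (i - 1, i):
            if 0 <= j < len(mz):
                d = abs(mz[j] - cmz)
                if bestd is None or d < bestd:
                    best, bestd = hills[j], d
        if bestd is not None and bestd / cmz * 1e6 <= tol_ppm:
            out[cid] = best
    return out
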