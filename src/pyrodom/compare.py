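"""Burn-severity group comparisons on assigned DOM formulas.

This is the statistical layer of the pipeline: it turns the assigned
formula table into a formula x sample presence matrix, derives the
formulas unique to each (possibly merged) severity group, compares
per-sample mean aromaticity across the severity gradient with one-sided
Welch t-tests (Holm-adjusted), and summarizes the nominal oxidation state
of carbon of each group's unique formulas (medians, histogram densities,
pairwise tests).

The layer is exposed both as the flat functions ``build_presence`` /
``unique_formulas`` / ``compare_ai`` / ``summarize_nosc`` and as a
model-style object: ``SeverityComparison(...).fit()`` returns a
:class:`SeverityComparisonResults` carrying all of the above with a
``summary()`` table.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PresenceMatrix",
    "build_presence",
    "unique_formulas",
    "compare_ai",
    "summarize_nosc",
    "SeverityComparison",
    "SeverityComparisonResults",
]

logger = logging.getLogger(__name__)

DEFAULT_SEVERITY_ORDER: tuple[str, ...] = ("control", "low", "moderate", "high")


@dataclass
class PresenceMatrix:
    """Boolean formula x sample detection matrix plus sample metadata."""

    detected: pd.DataFrame  # index: formula hill string; columns: sample_id
    metadata: pd.DataFrame  # index: sample_id; columns condition, depth, ...
    dropped: list[str] = field(default_factory=list)

    def samples_of(self, condition: str) -> list[str]:
        md = self.metadata
        return list(md.index[md["condition"] == condition])

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["condition"]))

    def occupancy(self) -> dict[str, set[str]]:
        """Map formula -> set of conditions with >= 1 detection."""
        cond = self.metadata["condition"]
        out: dict[str, set[str]] = {}
        for c in self.conditions():
            cols = cond.index[cond == c]
            hit = self.detected[cols].any(axis=1)
            for f in self.detected.index[hit]:
                out.setdefault(f, set()).add(c)
        return out


def build_presence(aft, metadata: pd.DataFrame) -> PresenceMatrix:
    """Presence matrix from an assigned table and a sample metadata frame.

    ``detected(f, s)`` is true iff formula f was assigned to a cluster in
    which sample s contributed a peak.  Clusters sharing a formula are
    OR-merged; formulas detected nowhere are dropped with a log entry.
    """
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    df = aft.table if hasattr(aft, "table") else aft
    samples = [s for s in md.index if s in df.columns]
    if not samples:
        raise ValueError("no metadata sample ids match assigned-table columns")
    assigned = df[df["formula"].notna()]
    pres = assigned[samples].notna()
    pres.index = assigned["formula"]
    pres = pres.groupby(level=0).any()
    empty = list(pres.index[~pres.any(axis=1)])
    if empty:
        logger.info("dropping %d formulas detected in no sample", len(empty))
        pres = pres.drop(index=empty)
    return PresenceMatrix(detected=pres, metadata=md.loc[samples], dropped=empty)


def _resolve_grouping(
    pm: PresenceMatrix, grouping: Mapping[str, str] | None
) -> dict[str, str]:
    conds = pm.conditions()
    if grouping is None:
        return {c: c for c in conds}
    missing = [c for c in conds if c not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover conditions: {missing}")
    return dict(grouping)


def unique_formulas(
    pm: PresenceMatrix, grouping: Mapping[str, str] | None = None
) -> dict[str, set[str]]:
    """Formulas detected in exactly one group (>= 1 sample there, 0 elsewhere).

    ``grouping`` maps each condition to a group label, allowing merged
    groups (e.g. moderate+high combined); by default every condition is
    its own group.  The returned sets are pairwise disjoint.
    """
    grouping = _resolve_grouping(pm, grouping)
    groups = sorted(set(grouping.values()))
    cond = pm.metadata["condition"]
    by_group = {}
    for g in groups:
        cols = [s for s in pm.detected.columns if grouping[cond[s]] == g]
        by_group[g] = pm.detected[cols].any(axis=1)
    hit_count = sum(b.astype(int) for b in by_group.values())
    return {
        g: set(pm.detected.index[by_group[g] & (hit_count == 1)]) for g in groups
    }


def _welch(x: np.ndarray, y: np.ndarray, alternative: str, equal_var: bool):
    res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _severity_pairs(conditions: Sequence[str], order: Sequence[str]):
    ranked = [c for c in order if c in conditions]
    return list(itertools.combinations(ranked, 2))


def compare_ai(
    pm: PresenceMatrix,
    ai_by_formula: pd.Series,
    pairs: Sequence[tuple[str, str]] | None = None,
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    alternative: str = "greater_with_severity",
    equal_var: bool = False,
    intensity_weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise one-sided tests on per-sample mean aromaticity index.

    The per-sample statistic is the unweighted mean AI over the formulas
    detected in that sample (or an intensity-weighted mean when
    ``intensity_weights`` is given).  For each condition pair ordered by
    severity, a Welch t-test (pooled-variance with ``equal_var=True``)
    tests H1: the more severe condition has higher mean AI; p-values are
    Holm-adjusted across pairs.  Conditions with fewer than 2 samples are
    skipped with a warning.

    Returns a frame with one row per tested pair: sample sizes, group
    means, t, p_raw, p_holm.
    """
    ai = ai_by_formula.dropna()
    common = pm.detected.index.intersection(ai.index)
    det = pm.detected.loc[common]
    sample_means = {}
    for s in det.columns:
        mask = det[s].to_numpy()
        vals = ai.loc[common].to_numpy()[mask]
        if intensity_weights is not None:
            w = intensity_weights.reindex(index=common)[s].to_numpy()[mask]
            sample_means[s] = float(np.average(vals, weights=w))
        else:
            sample_means[s] = float(vals.mean()) if len(vals) else np.nan
    means = pd.Series(sample_means, name="mean_ai")

    pairs = pairs or _severity_pairs(pm.conditions(), severity_order)
    rows = []
    for lo, hi in pairs:
        x_lo = means[pm.samples_of(lo)].dropna().to_numpy()
        x_hi = means[pm.samples_of(hi)].dropna().to_numpy()
        if len(x_lo) < 2 or len(x_hi) < 2:
            warnings.warn(f"pair ({lo}, {hi}) skipped: fewer than 2 samples")
            continue
        alt = "greater" if alternative == "greater_with_severity" else alternative
        t, p = _welch(x_hi, x_lo, alt, equal_var)
        rows.append(
            {
                "condition_low": lo, "condition_high": hi,
                "n_low": len(x_lo), "n_high": len(x_hi),
                "mean_low": float(x_lo.mean()), "mean_high": float(x_hi.mean()),
                "t": t, "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    out.attrs["sample_means"] = means
    return out


def summarize_nosc(
    unique_sets: Mapping[str, set[str]],
    nosc_by_formula: pd.Series,
    pairs: Sequence[tuple[str, str]] | None = None,
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    alternative: str = "greater_with_severity",
    equal_var: bool = False,
    bins: int = 40,
    hist_range: tuple[float, float] = (-2.5, 2.5),
) -> dict:
    """Medians, densities and pairwise tests of unique-formula NOSC values.

    Groups with empty unique sets are excluded with a warning.  Returns a
    dict with ``medians`` (Series per group), ``tests`` (frame of pairwise
    Welch results, Holm-adjusted), and ``density`` (long frame of
    normalized histogram heights per group, a kernel-free density export).
    """
    nos = nosc_by_formula.dropna()
    values: dict[str, np.ndarray] = {}
    for g, fs in unique_sets.items():
        v = nos.reindex(sorted(fs)).dropna().to_numpy()
        if len(v) == 0:
            warnings.warn(f"group {g!r} has no unique formulas; excluded")
            continue
        values[g] = v
    medians = pd.Series({g: float(np.median(v)) for g, v in values.items()})

    dens_rows = []
    for g, v in values.items():
        hist, edges = np.histogram(v, bins=bins, range=hist_range, density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        dens_rows.append(pd.DataFrame({"group": g, "nosc": centers, "density": hist}))
    density = pd.concat(dens_rows, ignore_index=True) if dens_rows else pd.DataFrame()

    pairs = pairs or _severity_pairs(list(values), severity_order)
    rows = []
    for lo, hi in pairs:
        if lo not in values or hi not in values:
            continue
        alt = "greater" if alternative == "greater_with_severity" else alternative
        t, p = _welch(values[hi], values[lo], alt, equal_var)
        rows.append(
            {
                "group_low": lo, "group_high": hi,
                "n_low": len(values[lo]), "n_high": len(values[hi]),
                "median_low": float(np.median(values[lo])),
                "median_high": float(np.median(values[hi])),
                "median_diff": float(np.median(values[hi]) - np.median(values[lo])),
                "t": t, "p_raw": p,
            }
        )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_holm"] = multipletests(tests["p_raw"], method="holm")[1]
    return {"medians": medians, "tests": tests, "density": density}


class SeverityComparison:
    """Model-style wrapper over the severity-comparison layer.

    Parameters
    ----------
    presence : PresenceMatrix
    metrics : pd.DataFrame
        Per-formula metrics keyed by the ``formula`` column (the frame
        returned by :func:`pyrodom.metrics.annotate_table`).
    grouping : mapping, optional
        condition -> group label for the unique-formula analysis
        (defaults to one group per condition).
    ai_metric, nosc_metric : str
        Metric columns to compare (default ``ai_standard`` /
        ``nosc_standard``).
    """

    def __init__(
        self,
        presence: PresenceMatrix,
        metrics: pd.DataFrame,
        grouping: Mapping[str, str] | None = None,
        severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
        ai_metric: str = "ai_standard",
        nosc_metric: str = "nosc_standard",
    ):
        self.presence = presence
        self.grouping = grouping
        self.severity_order = tuple(severity_order)
        m = metrics[metrics["formula"].notna()].drop_duplicates("formula")
        self._ai = m.set_index("formula")[ai_metric].astype(float)
        self._nosc = m.set_index("formula")[nosc_metric].astype(float)

    def fit(
        self,
        pairs: Sequence[tuple[str, str]] | None = None,
        alternative: str = "greater_with_severity",
        equal_var: bool = False,
    ) -> "SeverityComparisonResults":
        ai_tests = compare_ai(
            self.presence, self._ai, pairs, self.severity_order,
            alternative, equal_var,
        )
        uniq = unique_formulas(self.presence, self.grouping)
        group_order = list(dict.fromkeys(
            (self.grouping or {c: c for c in self.severity_order}).get(c, c)
            for c in self.severity_order
            if c in self.presence.conditions()
        ))
        nosc_pairs = pairs if self.grouping is None else None
        nosc = summarize_nosc(
            uniq, self._nosc, nosc_pairs, group_order, alternative, equal_var
        )
        return SeverityComparisonResults(
            ai_tests=ai_tests,
            ai_sample_means=ai_tests.attrs.get("sample_means", pd.Series(dtype=float)),
            unique_sets=uniq,
            nosc_medians=nosc["medians"],
            nosc_tests=nosc["tests"],
            nosc_density=nosc["density"],
        )


@dataclass
class SeverityComparisonResults:
    """Estimates and tests from :meth:`SeverityComparison.fit`."""

    ai_tests: pd.DataFrame
    ai_sample_means: pd.Series
    unique_sets: dict[str, set[str]]
    nosc_medians: pd.Series
    nosc_tests: pd.DataFrame
    nosc_density: pd.DataFrame

    def summary(self) -> str:
        lines = ["Severity comparison of DOM molecular composition",
                 "=" * 48, "",
                 "Per-sample mean aromaticity index, one-sided Welch t-tests:"]
        if len(self.ai_tests):
            lines.append(
                self.ai_tests[
                    ["condition_low", "condition_high", "n_low", "n_high",
                     "mean_low", "mean_high", "t", "p_raw", "p_holm"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        lines += ["", "Unique formulas per group:"]
        for g in sorted(self.unique_sets):
            lines.append(f"  {g}: {len(self.unique_sets[g])}")
        lines += ["", "Unique-formula NOSC medians:"]
        for g, v in self.nosc_medians.items():
            lines.append(f"  {g}: {v:.4f}")
        if len(self.nosc_tests):
            lines += ["", "Unique-formula NOSC pairwise tests:"]
            lines.append(
                self.nosc_tests[
                    ["group_low", "group_high", "median_diff", "t", "p_raw", "p_holm"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)
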