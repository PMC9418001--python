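import numpy as np
import pandas as pd
import pytest

from pyrodom.compare import (
    PresenceMatrix,
    SeverityComparison,
    build_presence,
    compare_ai,
    summarize_nosc,
    unique_formulas,
)
from pyrodom.synthetic import SyntheticDesign, generate_formula_pool, sample_detection
from pyrodom.metrics import aromaticity_index, nosc

from _helpers import run_mini_pipeline
from _oracles import welch_one_sided_greater


def toy_presence(det: dict, conditions: dict) -> PresenceMatrix:
    detected = pd.DataFrame(det).T.astype(bool)
    md = pd.DataFrame(
        {"condition": pd.Series(conditions), "depth": "surface"}
    )
    md.index.name = "sample_id"
    return PresenceMatrix(detected=detected, metadata=md)


class TestBuildPresence:
    def test_direct_construction(self):
        aft = pd.DataFrame(
            {
                "cluster_id": [0, 1],
                "formula": ["C6H12O6", "C6H6"],
                "s1": [1.0, np.nan],
                "s2": [2.0, 3.0],
            }
        )
        md = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "condition": ["control", "high"]}
        )
        pm = build_presence(aft, md)
        assert pm.detected.loc["C6H12O6"].tolist() == [True, True]
        assert pm.detected.loc["C6H6"].tolist() == [False, True]

    def test_undetected_formula_dropped_and_logged(self):
        aft = pd.DataFrame(
            {"cluster_id": [0], "formula": ["C6H6"], "s1": [np.nan], "s2": [np.nan]}
        )
        md = pd.DataFrame({"sample_id": ["s1", "s2"], "condition": ["control", "high"]})
        pm = build_presence(aft, md)
        assert len(pm.detected) == 0
        assert pm.dropped == ["C6H6"]

    def test_full_detection_zero_noise_matches_ground_truth(self):
        """detection_prob=1, sd=0: the recovered presence matrix equals the
        generator's occupancy exactly."""
        design = SyntheticDesign(
            conditions=("control", "high"),
            replicates_per_condition=2,
            n_core_formulas=60,
            n_unique_formulas_per_condition=15,
            aromatic_fraction_by_condition={"control": 0.1, "high": 0.35},
            mass_error_sd_ppm=0.0,
            detection_prob=1.0,
            seed=21,
        )
        res = run_mini_pipeline(design)
        pm = res["presence"]
        gt = res["ground_truth"]
        truth = gt[~gt["is_isotopologue"]]
        want = truth.pivot_table(
            index="formula", columns="sample_id", values="mz", aggfunc="size"
        ).notna()
        got = pm.detected.sort_index()
        want = want.reindex(index=got.index, columns=got.columns).fillna(False)
        pd.testing.assert_frame_equal(got, want.astype(bool), check_names=False)


class TestUniqueFormulas:
    def pm(self):
        return toy_presence(
            {
                "f_ctrl": {"c1": 1, "c2": 0, "l1": 0, "h1": 0},
                "f_shared": {"c1": 1, "c2": 1, "l1": 1, "h1": 1},
                "f_low_high": {"c1": 0, "c2": 0, "l1": 1, "h1": 1},
                "f_high": {"c1": 0, "c2": 0, "l1": 0, "h1": 1},
            },
            {"c1": "control", "c2": "control", "l1": "low", "h1": "high"},
        )

    def test_condition_exclusive_formula_is_unique(self):
        uniq = unique_formulas(self.pm())
        assert uniq["control"] == {"f_ctrl"}
        assert uniq["high"] == {"f_high"}
        assert "f_shared" not in set().union(*uniq.values())

    def test_merged_grouping(self):
        grouping = {"control": "control", "low": "low+high", "high": "low+high"}
        uniq = unique_formulas(self.pm(), grouping)
        assert uniq["low+high"] == {"f_low_high", "f_high"}
        assert uniq["control"] == {"f_ctrl"}

    def test_single_group_collects_everything(self):
        grouping = {c: "all" for c in ("control", "low", "high")}
        uniq = unique_formulas(self.pm(), grouping)
        assert uniq == {"all": {"f_ctrl", "f_shared", "f_low_high", "f_high"}}

    def test_sets_pairwise_disjoint(self, rng):
        det = {
            f"f{i}": {s: bool(rng.integers(0, 2)) for s in ("a", "b", "c", "d")}
            for i in range(50)
        }
        pm = toy_presence(
            det, {"a": "control", "b": "low", "c": "moderate", "d": "high"}
        )
        uniq = unique_formulas(pm)
        sets = list(uniq.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]
        assert sum(len(s) for s in sets) <= len(pm.detected)


class TestCompareAI:
    def test_identical_groups_give_symmetric_null(self):
        # both conditions see the same detection patterns -> equal means
        det = {
            "f1": {"c1": 1, "c2": 0, "c3": 1, "h1": 1, "h2": 0, "h3": 1},
            "f2": {"c1": 0, "c2": 1, "c3": 1, "h1": 0, "h2": 1, "h3": 1},
            "f3": {"c1": 1, "c2": 1, "c3": 0, "h1": 1, "h2": 1, "h3": 0},
        }
        pm = toy_presence(
            det,
            {"c1": "control", "c2": "control", "c3": "control",
             "h1": "high", "h2": "high", "h3": "high"},
        )
        ai = pd.Series({"f1": 0.1, "f2": 0.5, "f3": 0.9})
        out = compare_ai(pm, ai)
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_raw"].iloc[0] == pytest.approx(0.5)

    def test_small_condition_skipped_with_warning(self):
        det = {"f1": {"c1": 1, "h1": 1, "h2": 1}}
        pm = toy_presence(
            det, {"c1": "control", "h1": "high", "h2": "high"}
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_ai(pm, pd.Series({"f1": 0.5}))
        assert len(out) == 0

    def test_planted_aromatic_effect_detected(self):
        """aromatic fraction 0.05 vs 0.40, n=6 vs 6: adjusted one-sided p
        for high > control is significant."""
        design = SyntheticDesign(
            conditions=("control", "high"),
            replicates_per_condition=6,
            n_core_formulas=150,
            n_unique_formulas_per_condition=80,
            aromatic_fraction_by_condition={"control": 0.05, "high": 0.40},
            seed=7,
        )
        pools = generate_formula_pool(design)
        rng = np.random.default_rng(7)
        det, conditions = {}, {}
        hills = {c: sorted(f.hill for f in pools[c]) for c in pools}
        all_hills = sorted(set(hills["control"]) | set(hills["high"]))
        for cond in design.conditions:
            members = set(hills[cond])
            for r in range(design.replicates(cond)):
                s = f"{cond}_{r}"
                conditions[s] = cond
                mask = rng.random(len(all_hills)) < design.detection_prob
                for h, m in zip(all_hills, mask):
                    det.setdefault(h, {})[s] = bool(m) and h in members
        pm = toy_presence(det, conditions)
        from pyrodom.formula import MolecularFormula

        ai = pd.Series(
            {h: aromaticity_index(MolecularFormula.from_string(h)) for h in all_hills}
        )
        out = compare_ai(pm, ai)
        assert out["p_holm"].iloc[0] < 0.05
        assert out["mean_high"].iloc[0] > out["mean_low"].iloc[0]


class TestSummarizeNosc:
    def test_welch_values_match_first_principles_oracle(self):
        """Fixed 5 vs 5 fixture; expected values frozen from the
        independent mean/variance/Satterthwaite computation."""
        hi = [5.1, 4.8, 5.6, 5.3, 4.9]
        lo = [4.2, 4.5, 4.1, 4.8, 4.3]
        uniq = {
            "low": {f"L{i}" for i in range(5)},
            "high": {f"H{i}" for i in range(5)},
        }
        vals = pd.Series(
            {**{f"L{i}": v for i, v in enumerate(lo)},
             **{f"H{i}": v for i, v in enumerate(hi)}}
        )
        out = summarize_nosc(uniq, vals, pairs=[("low", "high")])
        t, p = out["tests"][["t", "p_raw"]].iloc[0]
        assert t == pytest.approx(4.005551702879942, abs=1e-6)
        assert p == pytest.approx(0.0020441508055672394, abs=1e-6)
        # and the oracle itself agrees with itself on the same data
        t_o, p_o = welch_one_sided_greater(np.array(hi), np.array(lo))
        assert t == pytest.approx(t_o) and p == pytest.approx(p_o)

    def test_identical_value_distributions_are_null(self):
        uniq = {"a": {"x1", "x2", "x3"}, "b": {"y1", "y2", "y3"}}
        vals = pd.Series(
            {"x1": 0.0, "x2": 0.2, "x3": -0.2, "y1": 0.0, "y2": 0.2, "y3": -0.2}
        )
        out = summarize_nosc(uniq, vals, pairs=[("a", "b")])
        row = out["tests"].iloc[0]
        assert row["median_diff"] == 0.0
        assert row["p_raw"] == pytest.approx(0.5)

    def test_medians_and_density_export(self):
        uniq = {"a": {"x1", "x2", "x3"}, "b": {"y1", "y2", "y3"}}
        vals = pd.Series(
            {"x1": 0.0, "x2": 0.1, "x3": -0.1, "y1": 1.0, "y2": 1.1, "y3": 0.9}
        )
        out = summarize_nosc(uniq, vals, pairs=[("a", "b")])
        assert out["medians"]["a"] == pytest.approx(0.0)
        assert out["medians"]["b"] == pytest.approx(1.0)
        dens = out["density"]
        assert set(dens["group"]) == {"a", "b"}
        # histogram densities integrate to ~1 over the export range
        width = dens["nosc"].iloc[1] - dens["nosc"].iloc[0]
        assert dens[dens["group"] == "a"]["density"].sum() * width == pytest.approx(1.0)

    def test_empty_group_excluded_with_warning(self):
        uniq = {"a": {"x1", "x2"}, "b": set()}
        vals = pd.Series({"x1": 0.0, "x2": 0.1})
        with pytest.warns(UserWarning, match="excluded"):
            out = summarize_nosc(uniq, vals, pairs=[("a", "b")])
        assert list(out["medians"].index) == ["a"]
        assert len(out["tests"]) == 0


def test_holm_adjustment_never_decreases_p(mini_result):
    res = mini_result
    model = SeverityComparison(res["presence"], res["metrics"])
    fit = model.fit()
    assert (fit.ai_tests["p_holm"] >= fit.ai_tests["p_raw"] - 1e-15).all()
    assert (fit.nosc_tests["p_holm"] >= fit.nosc_tests["p_raw"] - 1e-15).all()
    # monotone: sorting by raw preserves order of adjusted
    s = fit.ai_tests.sort_values("p_raw")
    assert s["p_holm"].is_monotonic_increasing


def test_results_summary_mentions_key_sections(mini_result):
    fit = SeverityComparison(mini_result["presence"], mini_result["metrics"]).fit()
    text = fit.summary()
    assert "aromaticity" in text
    assert "NOSC medians" in text
    assert "control" in text and "high" in text
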