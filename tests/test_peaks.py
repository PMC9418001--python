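import numpy as np
import pandas as pd
import pytest

from pyrodom.constants import C13_C12_DELTA, PROTON_MASS
from pyrodom.peaks import (
    PeakList,
    align_peaks,
    filter_mz_window,
    recalibrate,
    remove_isotopologues,
)
from pyrodom.synthetic import SyntheticDesign, generate_formula_pool, synthesize_peaklists

from _oracles import single_linkage_clusters


def make_pl(mzs, intensities=None, sample_id="s1"):
    return PeakList(
        sample_id=sample_id,
        peaks=pd.DataFrame(
            {"mz": mzs, "intensity": intensities or [1.0] * len(mzs)}
        ),
    )


class TestWindowFilter:
    def test_keeps_only_in_window(self):
        res = filter_mz_window(make_pl([150.0, 350.0, 950.0]))
        assert list(res.peaklist.peaks["mz"]) == [350.0]
        assert list(res.removed["mz"]) == [150.0, 950.0]

    def test_boundaries_are_closed(self):
        res = filter_mz_window(make_pl([200.0, 900.0]))
        assert list(res.peaklist.peaks["mz"]) == [200.0, 900.0]

    def test_empty_input_passes_through(self):
        res = filter_mz_window(make_pl([]))
        assert len(res.peaklist) == 0 and len(res.removed) == 0

    def test_conservation(self, rng):
        pl = make_pl(sorted(rng.uniform(100, 1000, 50)))
        res = filter_mz_window(pl)
        assert len(res.peaklist) + len(res.removed) == len(pl)


class TestIsotopologueRemoval:
    def test_satellite_below_parent_removed(self):
        res = remove_isotopologues(make_pl([400.0, 401.0033548], [100.0, 1.1]))
        assert list(res.peaklist.peaks["mz"]) == [400.0]
        assert (res.removed["reason"] == "isotopologue").all()

    def test_more_intense_higher_peak_not_removed(self):
        res = remove_isotopologues(make_pl([400.0, 401.0033548], [1.1, 100.0]))
        assert len(res.peaklist) == 2

    def test_single_peak_unchanged(self):
        res = remove_isotopologues(make_pl([400.0]))
        assert len(res.peaklist) == 1

    def test_idempotent(self, rng):
        mzs = np.sort(rng.uniform(200, 900, 200))
        mzs = np.concatenate([mzs, mzs[:50] + C13_C12_DELTA])
        inten = rng.lognormal(10, 1, len(mzs))
        once = remove_isotopologues(make_pl(np.sort(mzs), list(inten)))
        twice = remove_isotopologues(once.peaklist)
        assert once.peaklist.peaks.equals(twice.peaklist.peaks)
        assert len(twice.removed) == 0

    def test_conservation(self, rng):
        pl = make_pl(np.sort(rng.uniform(200, 900, 100)))
        res = remove_isotopologues(pl)
        assert len(res.peaklist) + len(res.removed) == len(pl)


class TestAlignment:
    def test_identical_mz_across_samples_form_one_cluster(self):
        pls = [make_pl([400.0], sample_id=s) for s in ("a", "b", "c")]
        apt = align_peaks(pls)
        assert len(apt.consensus_mz) == 1
        assert apt.intensities.notna().sum().sum() == 3

    def test_two_ppm_apart_stay_separate(self):
        apt = align_peaks(
            [make_pl([400.0], sample_id="a"), make_pl([400.0008], sample_id="b")]
        )
        assert len(apt.consensus_mz) == 2

    def test_matches_single_linkage_oracle_on_separated_peaks(self, rng):
        """On data whose clusters are separated by more than the tolerance
        (spread within clusters well below it), greedy consensus clustering
        and brute-force single linkage give the same partition."""
        centers = np.sort(rng.uniform(200, 900, 30))
        centers = centers[np.diff(centers, prepend=0.0) / centers * 1e6 > 3.0]
        mzs, pls = [], []
        for k in range(4):
            offs = centers * (1 + rng.normal(0, 0.05e-6, len(centers)))
            mzs.extend(offs)
            pls.append(make_pl(np.sort(offs), sample_id=f"s{k}"))
        apt = align_peaks(pls, tol_ppm=0.5)
        oracle = single_linkage_clusters(np.array(mzs), 0.5)
        got = {
            frozenset(apt.members.loc[apt.members["cluster_id"] == c, "mz"])
            for c in apt.consensus_mz.index
        }
        want = {frozenset(np.array(mzs)[list(grp)]) for grp in oracle}
        assert got == want

    def test_chain_splits_when_drifting_past_consensus_tolerance(self):
        """A +0.3 ppm/step chain: members join while within 0.5 ppm of the
        running consensus; the fourth peak (0.6 ppm from it) starts a new
        cluster."""
        base = 500.0
        mzs = [base * (1 + k * 0.3e-6) for k in range(4)]
        pls = [make_pl([m], sample_id=f"s{k}") for k, m in enumerate(mzs)]
        apt = align_peaks(pls, tol_ppm=0.5)
        sizes = sorted(apt.members.groupby("cluster_id").size())
        assert sizes == [1, 3]

    def test_invariant_to_sample_order(self, rng):
        mz = np.sort(rng.uniform(200, 900, 80))
        pls = [
            make_pl(mz * (1 + rng.normal(0, 0.1e-6, len(mz))), sample_id=s)
            for s in ("a", "b", "c")
        ]
        fwd = align_peaks(pls)
        rev = align_peaks(pls[::-1])
        pd.testing.assert_series_equal(fwd.consensus_mz, rev.consensus_mz)
        pd.testing.assert_frame_equal(fwd.intensities, rev.intensities)

    def test_duplicate_sample_peaks_resolved_by_intensity(self):
        pl = make_pl([400.0, 400.00004], [1.0, 9.0])  # 0.1 ppm apart, same sample
        apt = align_peaks([pl], tol_ppm=0.5)
        assert len(apt.consensus_mz) == 1
        assert apt.intensities.iloc[0, 0] == 9.0
        assert len(apt.unresolved) == 1


def _one_zero_noise_sample(drift, seed=5):
    design = SyntheticDesign(
        n_core_formulas=250, n_unique_formulas_per_condition=0,
        conditions=("control",), replicates_per_condition=1,
        aromatic_fraction_by_condition={"control": 0.1},
        mass_error_sd_ppm=0.0, calibration_drift_ppm=drift,
        isotopologue_enabled=False, detection_prob=1.0, seed=seed,
    )
    pools = generate_formula_pool(design)
    pls, _ = synthesize_peaklists(pools, design)
    return pls[0]


class TestRecalibration:
    def test_zero_error_gives_identity_model(self):
        res = recalibrate(_one_zero_noise_sample(0.0))
        assert res.model.applied
        assert abs(res.model.a) < 0.01
        assert abs(res.model.b * 900) < 0.01

    def test_constant_drift_recovered(self):
        res = recalibrate(_one_zero_noise_sample(0.3))
        assert res.model.applied
        assert res.model.a + res.model.b * 500 == pytest.approx(0.3, abs=0.05)
        assert res.model.residual_rms_ppm < 0.05

    def test_linear_drift_recovered_across_range(self):
        res = recalibrate(_one_zero_noise_sample((0.2, 0.0003)))
        assert res.model.applied
        for mz in (200.0, 550.0, 900.0):
            assert res.model.ppm(mz) == pytest.approx(0.2 + 0.0003 * mz, abs=0.05)
        assert res.model.residual_rms_ppm < 0.05

    def test_too_few_anchors_yields_identity_with_warning(self):
        pl = _one_zero_noise_sample(0.3)
        anchors = [(m, m) for m in pl.peaks["mz"][:4]]
        with pytest.warns(UserWarning, match="recalibration skipped"):
            res = recalibrate(pl, anchor_series=anchors)
        assert not res.model.applied
        assert res.peaklist.peaks.equals(pl.peaks)
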