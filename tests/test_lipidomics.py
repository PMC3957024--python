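import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from raftlink import lipidomics, synthetic
from raftlink.config import SimulationConfig


def _table(rows, samples):
    """rows: list of (lipid_id, class, values)."""
    data = []
    for lid, cls, values in rows:
        row = {"lipid_id": lid, "class": cls, "acyl_carbons": 34, "double_bonds": 2,
               "hydroxylation": np.nan, "mode": "positive"}
        row.update(dict(zip(samples, values)))
        data.append(row)
    return pd.DataFrame(data)


SAMPLES = ["wildtype_r1", "wildtype_r2", "mutant_r1", "mutant_r2"]
DESIGN = pd.DataFrame(
    {"sample_id": SAMPLES, "genotype": ["wildtype", "wildtype", "mutant", "mutant"],
     "replicate": [1, 2, 1, 2]}
)


class TestMergeModes:
    def test_one_empty(self):
        t = _table([("PC(34:2)", "PC", [1, 2, 3, 4])], SAMPLES)
        out = lipidomics.merge_modes(t, pd.DataFrame())
        pd.testing.assert_frame_equal(out, t)

    def test_count_conservation(self):
        pos = _table([("PC(34:2)", "PC", [1, 2, 3, 4]), ("PE(36:1)", "PE", [1, 1, 1, 1])], SAMPLES)
        neg = _table([("PG(34:1)", "PG", [2, 2, 2, 2])], SAMPLES)
        assert len(lipidomics.merge_modes(pos, neg)) == 3

    def test_shared_species_mode_suffixed(self):
        pos = _table([("PC(34:2)", "PC", [1, 2, 3, 4])], SAMPLES)
        neg = _table([("PC(34:2)", "PC", [5, 6, 7, 8])], SAMPLES)
        out = lipidomics.merge_modes(pos, neg)
        assert sorted(out["lipid_id"]) == ["PC(34:2)[+]", "PC(34:2)[-]"]

    def test_conflicting_metadata_raises(self):
        pos = _table([("X", "PC", [1, 2, 3, 4])], SAMPLES)
        neg = _table([("X", "PE", [1, 2, 3, 4])], SAMPLES)
        with pytest.raises(ValueError, match="conflicting"):
            lipidomics.merge_modes(pos, neg)


class TestNormalizeLipids:
    def test_hand_computed_reference_set(self):
        # three constant lipids fall strictly below the median CV of the six
        # lipids: the denominator is the sum of the three constants per sample
        rows = [
            ("A", "PC", [1.0, 1.0, 1.0, 1.0]),
            ("B", "PE", [2.0, 2.0, 2.0, 2.0]),
            ("C", "PG", [3.0, 3.0, 3.0, 3.0]),
            ("D", "PS", [1.0, 10.0, 0.1, 5.0]),
            ("E", "PI", [9.0, 0.5, 4.0, 1.0]),
            ("F", "PC", [0.2, 7.0, 2.0, 0.1]),
        ]
        res = lipidomics.normalize_lipids(_table(rows, SAMPLES))
        assert sorted(res.reference_ids) == ["A", "B", "C"]
        out = res.table.set_index("lipid_id")
        np.testing.assert_allclose(out.loc["A", SAMPLES].to_numpy(dtype=float), 1 / 6)
        np.testing.assert_allclose(
            out.loc["D", SAMPLES].to_numpy(dtype=float), np.array([1, 10, 0.1, 5]) / 6)

    def test_tie_case_triggers_fallback(self):
        rows = [
            ("A", "PC", [1.0, 2.0, 1.0, 2.0]),
            ("B", "PE", [2.0, 4.0, 2.0, 4.0]),  # same CV as A
        ]
        res = lipidomics.normalize_lipids(_table(rows, SAMPLES))
        assert res.fallback_used
        assert sorted(res.reference_ids) == ["A", "B"]

    def test_tag_excluded_from_denominator_but_normalized(self):
        rows = [
            ("A", "PC", [1.0, 1.0, 1.0, 1.0]),
            ("B", "PE", [3.0, 3.0, 3.0, 3.0]),
            ("T", "TAG", [100.0, 100.0, 100.0, 100.0]),
        ]
        res = lipidomics.normalize_lipids(_table(rows, SAMPLES))
        assert "T" not in res.reference_ids
        out = res.table.set_index("lipid_id")
        np.testing.assert_allclose(out.loc["T", SAMPLES].to_numpy(dtype=float), 25.0)

    def test_scale_invariance_per_sample(self):
        config = SimulationConfig(seed=3)
        pos, neg, _ = synthetic.simulate_lipids(config)
        merged = lipidomics.merge_modes(pos, neg)
        r1 = lipidomics.normalize_lipids(merged)
        doubled = merged.copy()
        doubled[SAMPLES[0] if SAMPLES[0] in doubled.columns else "wildtype_r1"] *= 2.0
        r2 = lipidomics.normalize_lipids(doubled)
        cols = lipidomics.sample_columns(merged)
        np.testing.assert_allclose(
            r1.table[cols].to_numpy(dtype=float),
            r2.table[cols].to_numpy(dtype=float), rtol=1e-12)


class TestTransformLipids:
    def test_constant_lipid_maps_to_log2_shift(self):
        rows = [
            ("A", "PC", [0.1, 0.2, 0.3, 0.4]),
            ("B", "PE", [0.5, 0.5, 0.5, 0.5]),
        ]
        res = lipidomics.transform_lipids(_table(rows, SAMPLES))
        out = res.table.set_index("lipid_id")
        assert res.degenerate_ids == ["B"]
        np.testing.assert_allclose(
            out.loc["B", SAMPLES].to_numpy(dtype=float), np.log2(res.shift))

    def test_global_minimum_maps_to_zero(self):
        rng = np.random.default_rng(1)
        rows = [(f"L{i}", "PC", rng.uniform(0, 1, 4)) for i in range(5)]
        res = lipidomics.transform_lipids(_table(rows, SAMPLES))
        vals = res.table[SAMPLES].to_numpy(dtype=float)
        assert np.min(vals) == pytest.approx(0.0, abs=1e-12)

    def test_rank_preservation(self):
        rng = np.random.default_rng(2)
        rows = [(f"L{i}", "PC", rng.uniform(0, 1, 4)) for i in range(8)]
        table = _table(rows, SAMPLES)
        res = lipidomics.transform_lipids(table)
        for i in range(len(table)):
            raw = table.loc[i, SAMPLES].to_numpy(dtype=float)
            trans = res.table.loc[i, SAMPLES].to_numpy(dtype=float)
            rho = sps.spearmanr(raw, trans).statistic
            assert rho == pytest.approx(1.0)


class TestDifferentialLipids:
    def _prep(self, table):
        norm = lipidomics.normalize_lipids(table).table
        trans = lipidomics.transform_lipids(norm).table
        return norm, trans

    def test_identical_groups_nothing_significant(self):
        rows = [
            ("A", "PC", [0.1, 0.2, 0.1, 0.2]),
            ("B", "PE", [0.3, 0.4, 0.3, 0.4]),
            ("C", "PG", [0.2, 0.25, 0.2, 0.25]),
        ]
        norm, trans = self._prep(_table(rows, SAMPLES))
        res = lipidomics.differential_lipids(norm, trans, DESIGN)
        assert not res.species["significant"].any()
        np.testing.assert_allclose(res.species["log2_fc"], 0.0, atol=1e-9)

    def test_class_sums_conservation(self):
        config = SimulationConfig(seed=4)
        pos, neg, _ = synthetic.simulate_lipids(config)
        norm = lipidomics.normalize_lipids(lipidomics.merge_modes(pos, neg)).table
        cols = lipidomics.sample_columns(norm)
        class_sums = norm.groupby("class")[cols].sum()
        np.testing.assert_allclose(class_sums.sum(axis=0), norm[cols].sum(axis=0))

    def test_power_on_planted_fcs(self):
        detected = total = 0
        for seed in range(40):
            config = SimulationConfig(
                n_lipids_per_class=3, n_lipid_replicates=5,
                frac_lipids_differential=0.25, lipid_fc_log2=1.0,
                lipid_noise_cv=0.1, seed=seed,
            )
            pos, neg, truth = synthetic.simulate_lipids(config)
            merged = lipidomics.merge_modes(pos, neg)
            norm = lipidomics.normalize_lipids(merged).table
            trans = lipidomics.transform_lipids(norm).table
            res = lipidomics.differential_lipids(norm, trans, synthetic.lipid_design(config))
            base_ids = res.species["lipid_id"].str.replace(r"\[[+-]\]$", "", regex=True)
            sig_base = set(base_ids[res.species["significant"]])
            for lid in truth.differential_lipids:
                total += 1
                detected += lid in sig_base
        assert detected / total >= 0.8

    def test_type_one_error_calibrated(self):
        # null lipids at alpha 0.05: direct t-test calibration on raw tables
        rejections = trials = 0
        for seed in range(60):
            config = SimulationConfig(
                n_lipids_per_class=2, n_lipid_replicates=5,
                frac_lipids_differential=0.0, lipid_noise_cv=0.1, seed=1000 + seed,
            )
            pos, neg, _ = synthetic.simulate_lipids(config)
            merged = lipidomics.merge_modes(pos, neg)
            norm = lipidomics.normalize_lipids(merged).table
            trans = lipidomics.transform_lipids(norm).table
            res = lipidomics.differential_lipids(norm, trans, synthetic.lipid_design(config))
            rejections += int(res.species["significant"].sum())
            trials += len(res.species)
        rate = rejections / trials
        se = np.sqrt(0.05 * 0.95 / trials)
        assert rate <= 0.05 + 3 * se

    def test_missing_genotype_raises(self):
        rows = [("A", "PC", [0.1, 0.2, 0.1, 0.2]), ("B", "PE", [1, 2, 1, 2])]
        norm, trans = self._prep(_table(rows, SAMPLES))
        bad = DESIGN[DESIGN["genotype"] == "wildtype"]
        with pytest.raises(ValueError):
            lipidomics.differential_lipids(norm, trans, bad)


class TestRtCorrect:
    def _peaks(self, rts):
        return pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(len(rts))],
             "mz": np.linspace(400, 800, len(rts)), "rt": rts}
        )

    def _markers(self, observed, library):
        return pd.DataFrame(
            {"name": [f"m{i}" for i in range(len(observed))],
             "mz": np.linspace(400, 800, len(observed)),
             "observed_rt": observed, "library_rt": library}
        )

    def test_identity_markers_noop(self):
        peaks = self._peaks(np.array([1.0, 5.0, 9.0]))
        markers = self._markers([2.0, 8.0], [2.0, 8.0])
        out = lipidomics.rt_correct(peaks, markers)
        np.testing.assert_allclose(out["rt"], peaks["rt"])

    def test_uniform_offset_removed(self):
        peaks = self._peaks(np.array([1.0, 5.0, 9.0, 14.0]))
        markers = self._markers([3.0, 8.0, 12.0], [2.0, 7.0, 11.0])
        out = lipidomics.rt_correct(peaks, markers)
        np.testing.assert_allclose(out["rt"], peaks["rt"] - 1.0)

    def test_fewer_than_two_markers_identity(self):
        peaks = self._peaks(np.array([1.0, 2.0]))
        out = lipidomics.rt_correct(peaks, self._markers([3.0], [2.0]))
        np.testing.assert_allclose(out["rt"], peaks["rt"])

    def test_nonlinear_drift_roundtrip(self, lipid_library):
        drift = lambda rt: rt + 0.4 * np.sin(rt / 4.0) + 0.5
        peaks, markers = synthetic.simulate_peaks(
            lipid_library, drift=drift, marker_stride=2, seed=9)
        corrected = lipidomics.rt_correct(peaks, markers)
        residual = np.abs(corrected["rt"].to_numpy() - lipid_library["rt"].to_numpy())
        assert residual.max() < 0.05


class TestMatchLibrary:
    def test_exact_match(self):
        peaks = pd.DataFrame({"peak_id": ["p0"], "mz": [500.0], "rt": [5.0]})
        lib = pd.DataFrame({"name": ["X"], "mz": [500.0], "rt": [5.0]})
        res = lipidomics.match_library(peaks, lib)
        assert res.matches.iloc[0]["name"] == "X"

    def test_ppm_threshold(self):
        lib = pd.DataFrame({"name": ["X"], "mz": [500.0], "rt": [5.0]})
        peak = pd.DataFrame({"peak_id": ["p0"], "mz": [500.0 * (1 + 10e-6)], "rt": [5.0]})
        assert lipidomics.match_library(peak, lib, ppm_tol=5).matches.empty
        assert len(lipidomics.match_library(peak, lib, ppm_tol=15).matches) == 1

    def test_monotone_in_tolerances(self):
        rng = np.random.default_rng(5)
        peaks = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(30)],
             "mz": rng.uniform(400, 900, 30), "rt": rng.uniform(0, 16, 30)}
        )
        lib = pd.DataFrame(
            {"name": [f"L{i}" for i in range(10)],
             "mz": rng.uniform(400, 900, 10), "rt": rng.uniform(0, 16, 10)}
        )
        prev = None
        for ppm, rt in [(5, 0.25), (50, 0.5), (500, 1.0), (5000, 4.0)]:
            m = set(lipidomics.match_library(peaks, lib, ppm, rt).matches["peak_id"])
            if prev is not None:
                assert prev <= m
            prev = m

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        peaks = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(rng.integers(1, 10))]}
        )
        peaks["mz"] = rng.uniform(400, 500, len(peaks))
        peaks["rt"] = rng.uniform(0, 10, len(peaks))
        lib = pd.DataFrame({"name": [f"L{i}" for i in range(rng.integers(1, 10))]})
        lib["mz"] = rng.uniform(400, 500, len(lib))
        lib["rt"] = rng.uniform(0, 10, len(lib))
        ppm_tol, rt_tol = 2000.0, 1.0
        res = lipidomics.match_library(peaks, lib, ppm_tol, rt_tol)
        got = dict(zip(res.matches["peak_id"], res.matches["name"]))
        expected = {}
        for _, p in peaks.iterrows():
            best, key = None, None
            for _, l in lib.iterrows():
                ppm = abs(p["mz"] - l["mz"]) / l["mz"] * 1e6
                drt = abs(p["rt"] - l["rt"])
                if ppm <= ppm_tol and drt <= rt_tol:
                    if key is None or (ppm, drt) < key:
                        best, key = l["name"], (ppm, drt)
            if best is not None:
                expected[p["peak_id"]] = best
        assert got == expected

    def test_empty_inputs(self):
        res = lipidomics.match_library(pd.DataFrame(), pd.DataFrame())
        assert res.matches.empty
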