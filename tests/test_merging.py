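"""Ambiguity resolution, frame scaling, merging statistics, HKL export."""

import numpy as np
import pandas as pd
import pytest

from tserialed.exceptions import InsufficientDataError, InvalidArgumentError
from tserialed.geometry import UnitCell
from tserialed.merging import (
    completeness,
    merge,
    read_hkl,
    resolve_indexing_ambiguity,
    scale_frames,
    write_hkl,
)
from tserialed import symmetry


def _obs(rows):
    return pd.DataFrame(rows, columns=["frame_id", "h", "k", "l", "I", "sigma"])


class TestMergeStatistics:
    def test_hand_computed_toy_set(self):
        """Two uniques, hand-evaluated weighted means and R formulas."""
        obs = _obs(
            [
                (0, 1, 0, 0, 10.0, 1.0),
                (1, 1, 0, 0, 12.0, 1.0),
                (2, 1, 0, 0, 14.0, 1.0),
                (0, 2, 1, 0, 20.0, 2.0),
                (1, 2, 1, 0, 26.0, 1.0),
            ]
        )
        merged, stats = merge(obs, "-1", intensity_col="I", sigma_col="sigma")
        assert len(merged) == 2
        m = {(r.h, r.k, r.l): (r.I, r.sigma, r.multiplicity) for r in merged.itertuples()}
        # unique 1: unweighted mean 12, sigma 1/sqrt(3)
        assert m[(1, 0, 0)][0] == pytest.approx(12.0, abs=1e-12)
        assert m[(1, 0, 0)][1] == pytest.approx(1 / np.sqrt(3), abs=1e-12)
        # unique 2: weights 0.25 and 1 -> mean 24.8, sigma 1/sqrt(1.25)
        assert m[(2, 1, 0)][0] == pytest.approx(24.8, abs=1e-12)
        assert m[(2, 1, 0)][1] == pytest.approx(1 / np.sqrt(1.25), abs=1e-12)
        # deviation sums: |10-12|+|12-12|+|14-12| = 4 ; |20-24.8|+|26-24.8| = 6
        denom = 10 + 12 + 14 + 20 + 26
        assert stats.r_merge == pytest.approx(10.0 / denom, abs=1e-12)
        assert stats.r_meas == pytest.approx(
            (np.sqrt(3 / 2) * 4 + np.sqrt(2 / 1) * 6) / denom, abs=1e-12
        )
        assert stats.r_pim == pytest.approx(
            (np.sqrt(1 / 2) * 4 + np.sqrt(1 / 1) * 6) / denom, abs=1e-12
        )
        # halves in frame order: A={10,14} B={12} ; A={20} B={26}
        ia = np.array([(10 + 14) / 2, 20.0])
        ib = np.array([12.0, 26.0])
        assert stats.r_split == pytest.approx(
            np.sum(np.abs(ia - ib)) / (np.sqrt(2) * 0.5 * np.sum(ia + ib)), abs=1e-12
        )
        assert stats.cc_half == pytest.approx(1.0, abs=1e-12)
        assert stats.mean_multiplicity == pytest.approx(2.5)

    def test_identical_duplicates_give_zero_r(self):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(20):
            h, k, l = rng.integers(1, 5, 3)
            val = float(rng.uniform(10, 100))
            rows += [(0, h, k, l + i, val, 1.0), (1, h, k, l + i, val, 1.0)]
        _, stats = merge(_obs(rows), "-1", intensity_col="I", sigma_col="sigma")
        assert stats.r_merge == pytest.approx(0.0, abs=1e-12)
        assert stats.r_split == pytest.approx(0.0, abs=1e-12)
        assert stats.cc_half == pytest.approx(1.0, abs=1e-9)

    def test_multiplicity_identities_at_uniform_n(self, rng):
        """R_meas = sqrt(n/(n-1)) R_merge and R_pim = sqrt(1/(n-1)) R_merge."""
        n = 4
        rows = []
        for i in range(25):
            base = float(rng.uniform(20, 200))
            for f in range(n):
                rows.append((f, 1 + i, 2, 3, base * float(rng.uniform(0.8, 1.2)), 1.0))
        _, stats = merge(_obs(rows), "-1", intensity_col="I", sigma_col="sigma")
        assert stats.r_meas == pytest.approx(np.sqrt(n / (n - 1)) * stats.r_merge, rel=1e-12)
        assert stats.r_pim == pytest.approx(np.sqrt(1 / (n - 1)) * stats.r_merge, rel=1e-12)
        assert stats.r_meas >= stats.r_merge >= stats.r_pim >= 0

    def test_order_invariance(self, rng):
        rows = [
            (int(f), int(h), int(k), int(l), float(v), float(s))
            for f, h, k, l, v, s in zip(
                rng.integers(0, 6, 60),
                rng.integers(-4, 5, 60),
                rng.integers(-4, 5, 60),
                rng.integers(1, 5, 60),
                rng.uniform(5, 50, 60),
                rng.uniform(0.5, 2, 60),
            )
        ]
        obs = _obs(rows)
        shuffled = obs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        m1, s1 = merge(obs, "2/m", intensity_col="I", sigma_col="sigma")
        m2, s2 = merge(shuffled, "2/m", intensity_col="I", sigma_col="sigma")
        pd.testing.assert_frame_equal(m1, m2)
        assert s1.to_dict() == pytest.approx(s2.to_dict(), nan_ok=True)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            merge(_obs([]), "-1")


class TestScaleFrames:
    def test_identical_frames_get_equal_scales(self):
        rows = [(f, h, 0, 1, 30.0, 1.0) for f in (0, 1) for h in range(1, 6)]
        scales = scale_frames(_obs(rows), "-1", intensity_col="I", sigma_col="sigma")
        assert scales.loc[0] == pytest.approx(1.0)
        assert scales.loc[1] == pytest.approx(1.0, abs=1e-9)

    def test_doubled_frame_converges_to_two(self):
        rows = [(0, h, 0, 1, 30.0 + h, 1.0) for h in range(1, 8)]
        rows += [(1, h, 0, 1, 2 * (30.0 + h), 1.0) for h in range(1, 8)]
        scales = scale_frames(_obs(rows), "-1", intensity_col="I", sigma_col="sigma")
        assert scales.loc[1] == pytest.approx(2.0, rel=1e-6)

    def test_lognormal_jitter_recovered(self, rng):
        """Injected per-frame scales correlate with the fitted ones, r > 0.95."""
        true_means = {h: float(rng.uniform(10, 100)) for h in range(1, 40)}
        true_scales = np.exp(rng.normal(0, 0.2, 15))
        rows = []
        for f, kf in enumerate(true_scales):
            for h in rng.choice(list(true_means), size=25, replace=False):
                val = kf * true_means[h] * float(rng.normal(1, 0.03))
                rows.append((f, int(h), 0, 1, val, 1.0))
        scales = scale_frames(_obs(rows), "-1", intensity_col="I", sigma_col="sigma")
        fitted = scales.loc[np.arange(15)].to_numpy()
        r = np.corrcoef(true_scales / true_scales[0], fitted)[0, 1]
        assert r > 0.95

    def test_disconnected_components_warn(self):
        rows = [(0, 1, 0, 0, 10.0, 1.0), (1, 1, 0, 0, 11.0, 1.0),
                (2, 9, 9, 9, 5.0, 1.0), (3, 9, 9, 9, 6.0, 1.0)]
        with pytest.warns(UserWarning, match="disconnected"):
            scale_frames(_obs(rows), "-1", intensity_col="I", sigma_col="sigma")


class TestAmbiguityResolution:
    def test_triclinic_without_operators_unchanged(self):
        ds = [_obs([(0, 1, 2, 3, 10.0, 1.0)]), _obs([(1, 1, 2, 3, 12.0, 1.0)])]
        out, ops, flags = resolve_indexing_ambiguity(ds, [np.eye(3, dtype=int)], "-1")
        assert ops == [0, 0]
        pd.testing.assert_frame_equal(out[0], ds[0])

    def test_synthetic_twin_recovered(self, rng):
        """Half the datasets arrive reindexed by a known operator; resolution
        makes all consistent up to a global choice."""
        op = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])
        uniques = {tuple(v): float(rng.exponential(50)) for v in rng.integers(-5, 6, (200, 3)) if any(v)}
        keys = list(uniques)
        datasets, truth_twinned = [], []
        for d in range(40):
            chosen = [keys[i] for i in rng.choice(len(keys), 40, replace=False)]
            hkl = np.array(chosen)
            vals = np.array([uniques[c] for c in chosen]) * rng.normal(1, 0.05, len(chosen))
            twin = d % 2 == 1
            if twin:
                hkl = hkl @ op.T
            truth_twinned.append(twin)
            datasets.append(
                pd.DataFrame({"frame_id": d, "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                              "I": vals, "sigma": 1.0})
            )
        out, ops, flags = resolve_indexing_ambiguity(datasets, [np.eye(3, dtype=int), op], "-1",
                                                     intensity_col="I")
        assigned = np.array(ops)
        want = np.array(truth_twinned, dtype=int)
        # agreement up to the global two-fold choice
        assert np.array_equal(assigned, want) or np.array_equal(assigned, 1 - want)
        assert not any(flags)

    def test_idempotent(self, rng):
        op = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])
        ds = [
            pd.DataFrame({"frame_id": d, "h": [1, 2, 3, 1], "k": [0, 1, 1, 2],
                          "l": [1, 1, 2, 2], "I": rng.uniform(5, 50, 4), "sigma": 1.0})
            for d in range(4)
        ]
        once, ops1, _ = resolve_indexing_ambiguity(ds, [np.eye(3, dtype=int), op], "-1",
                                                   intensity_col="I")
        twice, ops2, _ = resolve_indexing_ambiguity(once, [np.eye(3, dtype=int), op], "-1",
                                                    intensity_col="I")
        assert ops2 == [0] * 4
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a, b)


class TestCompleteness:
    def test_full_coverage_is_one(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        expected = symmetry.enumerate_unique_reflections(cell, "-1", 2.0)
        assert completeness(expected, cell, "-1", 2.0) == 1.0

    def test_exact_half_coverage(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        expected = symmetry.enumerate_unique_reflections(cell, "-1", 2.0)
        half = expected[: len(expected) // 2]
        assert completeness(half, cell, "-1", 2.0) == pytest.approx(
            (len(expected) // 2) / len(expected)
        )

    def test_degenerate_resolution_warns(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        with pytest.warns(UserWarning):
            completeness(np.array([[1, 0, 0]]), cell, "-1", d_min=25.0)


class TestHKLExport:
    def test_round_trip(self, tmp_path, rng):
        refls = pd.DataFrame(
            {
                "h": rng.integers(-20, 20, 30),
                "k": rng.integers(-20, 20, 30),
                "l": rng.integers(-20, 20, 30),
                "I": rng.uniform(-5, 5000, 30),
                "sigma": rng.uniform(0.1, 50, 30),
            }
        )
        path = write_hkl(refls, tmp_path / "t.hkl")
        back = read_hkl(path)
        assert np.array_equal(back[["h", "k", "l"]], refls[["h", "k", "l"]])
        assert np.allclose(back["I"], refls["I"], atol=0.005)
        assert np.allclose(back["sigma"], refls["sigma"], atol=0.005)

    def test_byte_exact_against_handwritten_fixture(self, tmp_path):
        refls = pd.DataFrame(
            {
                "h": [1, -1, 10],
                "k": [2, 0, -10],
                "l": [3, 2, 5],
                "I": [123.45, 0.5, 999.99],
                "sigma": [6.78, 0.25, 99.99],
            }
        )
        path = write_hkl(refls, tmp_path / "fixed.hkl")
        expected = (
            "   1   2   3  123.45    6.78\n"
            "  -1   0   2    0.50    0.25\n"
            "  10 -10   5  999.99   99.99\n"
            "   0   0   0    0.00    0.00\n"
        )
        assert path.read_text() == expected

    def test_empty_list_writes_terminator_with_warning(self, tmp_path):
        with pytest.warns(UserWarning):
            path = write_hkl(pd.DataFrame(columns=["h", "k", "l", "I", "sigma"]), tmp_path / "e.hkl")
        assert path.read_text() == "   0   0   0    0.00    0.00\n"

    def test_out_of_range_index_rejected(self, tmp_path):
        refls = pd.DataFrame({"h": [1000], "k": [0], "l": [0], "I": [1.0], "sigma": [1.0]})
        with pytest.raises(InvalidArgumentError):
            write_hkl(refls, tmp_path / "x.hkl")

    def test_overflow_rescaled(self, tmp_path):
        refls = pd.DataFrame(
            {"h": [1, 2], "k": [0, 0], "l": [0, 0], "I": [2e6, 1e6], "sigma": [10.0, 5.0]}
        )
        path = write_hkl(refls, tmp_path / "big.hkl")
        back = read_hkl(path)
        assert back["I"].max() <= 99999.99
        assert back["I"][0] / back["I"][1] == pytest.approx(2.0, rel=1e-3)
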