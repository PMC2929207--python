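"""Peak lists, calibration, clustering into the analysis matrix, and I/O."""

import numpy as np
import pytest

from peptidiff import (
    AnalysisMatrix,
    PeakList,
    build_matrix,
    calibrate_peaklist,
    hsa_reference_mzs,
    read_groups,
    read_matrix,
    write_groups,
    write_matrix,
)
from peptidiff.errors import CalibrationError, ConfigurationError, MatrixParseError
from peptidiff.matrix import matrices_equal, read_peaklist, write_peaklist

from conftest import make_matrix

REFS = hsa_reference_mzs()


def brute_force_clusters(mzs, tol_ppm):
    """Oracle: exhaustive pairwise single linkage via union-find."""
    n = len(mzs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(1e6 * (mzs[i] - mzs[j]) / min(mzs[i], mzs[j])) <= tol_ppm:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(mzs[i])
    return sorted(tuple(sorted(v)) for v in groups.values())


class TestPeakList:
    def test_peaks_sorted_on_construction(self):
        pl = PeakList("s", mz=[1200.0, 1000.0], intensity=[2.0, 1.0])
        assert list(pl.mz) == [1000.0, 1200.0]
        assert list(pl.intensity) == [1.0, 2.0]

    def test_duplicate_mz_rejected(self):
        with pytest.raises(ConfigurationError):
            PeakList("s", mz=[1000.0, 1000.0 + 1e-8], intensity=[1.0, 2.0])

    def test_roundtrip_via_delimited_text(self, tmp_path):
        pl = PeakList("s1", mz=[1000.5, 1200.25], intensity=[3.0, 4.0], sn=[10.0, 20.0])
        path = tmp_path / "s1.tsv"
        write_peaklist(pl, path)
        back = read_peaklist(path)
        assert back.sample_id == "s1"
        np.testing.assert_allclose(back.mz, pl.mz)
        np.testing.assert_allclose(back.sn, pl.sn)


class TestCalibration:
    def test_already_calibrated_gives_identity_transform(self):
        pl = PeakList("s", mz=REFS, intensity=np.ones(5))
        cal, model = calibrate_peaklist(pl, REFS, match_tol_ppm=20)
        assert model.slope == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(cal.mz, pl.mz, rtol=1e-12)

    def test_uniform_drift_recovered_within_tenth_ppm(self):
        truth = np.array(REFS + [900.123, 1500.456])
        drifted = truth * (1 + 15e-6)
        pl = PeakList("s", mz=drifted, intensity=np.ones(truth.size))
        cal, model = calibrate_peaklist(pl, REFS, match_tol_ppm=20)
        err_ppm = 1e6 * (np.sort(cal.mz) - np.sort(truth)) / np.sort(truth)
        assert np.max(np.abs(err_ppm)) < 0.1
        assert model.n_refs_matched == 5

    def test_rms_residual_not_worse_after_calibration(self):
        rng = np.random.default_rng(0)
        noisy = np.array(REFS) * (1 + 8e-6) + rng.normal(0, 5e-4, 5)
        pl = PeakList("s", mz=noisy, intensity=np.ones(5))
        _, model = calibrate_peaklist(pl, REFS, match_tol_ppm=20)
        pre = 1e6 * (noisy - np.array(sorted(REFS))) / np.array(sorted(REFS))
        assert np.sqrt(np.mean(np.square(model.residuals_ppm))) <= np.sqrt(
            np.mean(pre**2)
        )

    def test_single_matched_reference_raises_with_count(self):
        pl = PeakList("s", mz=[REFS[0], 2222.2], intensity=[1.0, 1.0])
        with pytest.raises(CalibrationError) as exc:
            calibrate_peaklist(pl, REFS, match_tol_ppm=20)
        assert exc.value.n_matched == 1

    def test_calibration_is_idempotent(self):
        drifted = np.array(REFS) * (1 + 12e-6)
        pl = PeakList("s", mz=drifted, intensity=np.ones(5))
        once, _ = calibrate_peaklist(pl, REFS, 20)
        twice, _ = calibrate_peaklist(once, REFS, 20)
        shift_ppm = 1e6 * np.abs(twice.mz - once.mz) / once.mz
        assert np.max(shift_ppm) < 0.1


class TestBuildMatrix:
    def test_identical_lists_give_dense_matrix(self):
        mz = 1000.0 + 50.0 * np.arange(10)
        pls = [
            PeakList(s, mz=mz, intensity=np.ones(10)) for s in ("a", "b")
        ]
        m = build_matrix(pls, 5.0, {"a": "A", "b": "B"})
        assert m.n_peaks == 10 and m.n_samples == 2
        assert not np.isnan(m.intensities.to_numpy()).any()

    def test_gap_above_tolerance_splits_rows(self):
        # 30 ppm apart at 1000 u with 10 ppm tolerance -> two rows
        pls = [
            PeakList("a", mz=[1000.0000], intensity=[1.0]),
            PeakList("b", mz=[1000.0300], intensity=[1.0]),
        ]
        m = build_matrix(pls, 10.0, {"a": "A", "b": "B"})
        assert m.n_peaks == 2

    def test_gap_below_tolerance_merges_with_weighted_consensus(self):
        pls = [
            PeakList("a", mz=[1000.0000], intensity=[1.0]),
            PeakList("b", mz=[1000.0050], intensity=[3.0]),
        ]
        m = build_matrix(pls, 10.0, {"a": "A", "b": "B"})
        assert m.n_peaks == 1
        assert m.peak_mzs[0] == pytest.approx(
            (1000.0 * 1.0 + 1000.005 * 3.0) / 4.0, abs=1e-9
        )

    def test_clustering_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            mzs = np.sort(rng.uniform(1000, 1000.5, 24))
            mzs += np.arange(24) * 1e-7  # avoid duplicates
            half = PeakList("a", mz=mzs[::2], intensity=np.ones(12))
            other = PeakList("b", mz=mzs[1::2], intensity=np.ones(12))
            m = build_matrix([half, other], 40.0, {"a": "A", "b": "B"})
            oracle = brute_force_clusters(list(mzs), 40.0)
            assert m.n_peaks == len(oracle)
            for consensus, cluster in zip(m.peak_mzs, oracle):
                assert consensus == pytest.approx(np.mean(cluster), abs=1e-9)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        pls = [
            PeakList(
                f"s{i}",
                mz=np.sort(rng.uniform(900, 1100, 15)),
                intensity=rng.lognormal(2, 1, 15),
            )
            for i in range(4)
        ]
        groups = {f"s{i}": "G" for i in range(4)}
        m1 = build_matrix(pls, 5.0, groups)
        m2 = build_matrix(pls[::-1], 5.0, groups)
        assert np.allclose(m1.peak_mzs, m2.peak_mzs)
        assert m1.intensities[m2.sample_ids[::-1]].equals(
            m2.intensities[m2.sample_ids[::-1]]
        )

    def test_missing_group_label_names_sample(self):
        pls = [
            PeakList("a", mz=[1000.0], intensity=[1.0]),
            PeakList("b", mz=[1000.0], intensity=[1.0]),
        ]
        with pytest.raises(ConfigurationError, match="'b'"):
            build_matrix(pls, 5.0, {"a": "A"})


class TestMatrixIO:
    def _synthetic(self, n_peaks=100, n_samples=31):
        rng = np.random.default_rng(9)
        cols = {}
        groups = {}
        for i in range(n_samples):
            group = "PP" if i < 10 else "RR" if i < 21 else "control"
            sid = f"{group}_{i:02d}"
            vals = rng.lognormal(5, 1, n_peaks)
            vals[rng.uniform(size=n_peaks) < 0.2] = np.nan
            cols[sid] = vals
            groups[sid] = group
        mzs = np.sort(rng.uniform(700, 3500, n_peaks))
        return make_matrix(cols, groups, mzs=mzs)

    @pytest.mark.parametrize(
        "suffix, rtol",
        [
            (".tsv", 0.0),  # text dialect: bit-exact round trip
            (".xlsx", 1e-14),  # XLSX stores 15 significant digits
        ],
    )
    def test_roundtrip_with_absences(self, tmp_path, suffix, rtol):
        m = self._synthetic()
        path = tmp_path / f"matrix{suffix}"
        write_matrix(m, path)
        back = read_matrix(path, m.groups)
        assert matrices_equal(m, back, rtol=rtol)

    def test_duplicate_sample_column_raises(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("m/z\ts1\ts1\n1000.0\t1.0\t2.0\n")
        with pytest.raises(MatrixParseError):
            read_matrix(path, {"s1": "A"})

    def test_non_numeric_cell_raises_with_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("m/z\ts1\ts2\n1000.0\tok?\t2.0\n")
        with pytest.raises(MatrixParseError) as exc:
            read_matrix(path, {"s1": "A", "s2": "A"})
        assert exc.value.column == "s1"

    def test_cohort_sample_sheet_gives_study_group_sizes(self, tmp_path):
        m = self._synthetic(n_peaks=5, n_samples=31)
        sheet = tmp_path / "groups.tsv"
        write_groups(m.groups, sheet)
        groups = read_groups(sheet)
        mpath = tmp_path / "m.tsv"
        write_matrix(m, mpath)
        back = read_matrix(mpath, groups)
        assert back.group_sizes() == {"PP": 10, "RR": 11, "control": 10}
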