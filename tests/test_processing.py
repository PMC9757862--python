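"""Annotation, filters, normalization and peak-list I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dnlipid import masslist as mlmod
from dnlipid import processing as proc
from dnlipid import synthetic as syn

from conftest import random_peaklist


def make_masslist(mzs, polarity="positive"):
    """Mass list with arbitrary theoretical m/z values (distinct PC species)."""
    adduct = (
        mlmod.KNOWN_ADDUCTS["[M+H]+"]
        if polarity == "positive"
        else mlmod.KNOWN_ADDUCTS["[M-H]-"]
    )
    entries = []
    for i, mz in enumerate(mzs):
        sp = mlmod.LipidSpecies("PC", 28 + 2 * i, 0)
        entries.append(mlmod.MassListEntry(mz, sp, adduct))
    entries.sort(key=lambda e: e.mz)
    return mlmod.MassList(entries, polarity)


def brute_force_annotate(pl, ml, tol_ppm=9.0):
    """All-pairs nearest-within-tolerance matcher (independent oracle)."""
    out = {}
    for e in ml.entries:
        best = None
        for i in range(len(pl)):
            ppm = (pl.mz[i] - e.mz) / e.mz * 1e6
            if abs(ppm) <= tol_ppm:
                key = (abs(ppm), -pl.intensity[i])
                if best is None or key < best[0]:
                    best = (key, i, ppm)
        if best is not None:
            out[e.variable_id] = (best[1], best[2])
    return out


class TestAnnotatePeaks:
    def test_ppm_deviation_inside_window_retained(self):
        ml = make_masslist([806.7363])
        pl = proc.PeakList("s", "positive", np.array([806.7300]), np.array([50.0]),
                           noise_level=1.0)
        sigs = proc.annotate_peaks(pl, ml)
        assert len(sigs) == 1
        assert sigs[0].ppm_deviation == pytest.approx(-7.81, abs=0.01)

    def test_deviation_beyond_nine_ppm_ignored(self):
        ml = make_masslist([806.7363])
        pl = proc.PeakList("s", "positive", np.array([806.7290]), np.array([50.0]),
                           noise_level=1.0)
        assert proc.annotate_peaks(pl, ml) == []

    def test_exact_match_zero_ppm(self):
        ml = make_masslist([700.0])
        pl = proc.PeakList("s", "positive", np.array([700.0]), np.array([5.0]),
                           noise_level=1.0)
        sigs = proc.annotate_peaks(pl, ml)
        assert sigs[0].ppm_deviation == 0.0
        assert sigs[0].snr == 5.0

    def test_nearest_peak_wins(self):
        ml = make_masslist([700.0])
        pl = proc.PeakList(
            "s", "positive",
            np.array([699.9970, 700.0020]), np.array([10.0, 99.0]),
            noise_level=1.0,
        )
        sigs = proc.annotate_peaks(pl, ml)
        assert sigs[0].observed_mz == pytest.approx(700.0020)

    def test_exact_tie_broken_by_intensity(self):
        ml = make_masslist([700.0])
        pl = proc.PeakList(
            "s", "positive",
            np.array([699.998, 700.002]), np.array([10.0, 99.0]),
            noise_level=1.0,
        )
        sigs = proc.annotate_peaks(pl, ml)
        assert sigs[0].observed_mz == pytest.approx(700.002)

    def test_polarity_mismatch_rejected(self):
        ml = make_masslist([700.0], "negative")
        pl = proc.PeakList("s", "positive", np.array([700.0]), np.array([1.0]),
                           noise_level=1.0)
        with pytest.raises(ValueError, match="polarity"):
            proc.annotate_peaks(pl, ml)

    def test_noise_estimated_from_unannotated_peaks(self):
        ml = make_masslist([700.0])
        pl = proc.PeakList(
            "s", "positive",
            np.array([300.0, 400.0, 500.0, 700.0]),
            np.array([4.0, 8.0, 6.0, 60.0]),
        )
        sigs = proc.annotate_peaks(pl, ml)
        assert sigs[0].snr == pytest.approx(10.0)  # 60 / median(4, 8, 6)

    @pytest.mark.parametrize("n_peaks,n_entries,seed", [(50, 20, 0), (200, 80, 1)])
    def test_matches_bruteforce_oracle(self, n_peaks, n_entries, seed):
        rng = np.random.default_rng(seed)
        pl = random_peaklist(rng, n_peaks)
        mzs = np.sort(rng.uniform(150.0, 1200.0, n_entries))
        # include near-duplicates of observed peaks to exercise the window
        mzs[: n_peaks // 10] = np.sort(
            rng.choice(pl.mz, n_peaks // 10, replace=False)
            * (1 + rng.normal(0, 5e-6, n_peaks // 10))
        )
        ml = make_masslist(np.sort(mzs))
        ours = {
            s.variable_id: s.ppm_deviation for s in proc.annotate_peaks(pl, ml)
        }
        oracle = {k: v[1] for k, v in brute_force_annotate(pl, ml).items()}
        assert set(ours) == set(oracle)
        for k in ours:
            assert ours[k] == pytest.approx(oracle[k], abs=1e-9)


class TestSnrFilter:
    def test_boundary(self):
        ml = make_masslist([700.0, 800.0])
        mk = lambda snr: proc.AnnotatedSignal(
            ml.entries[0].species, ml.entries[0].adduct, 700.0, 0.0, snr * 10, snr
        )
        assert proc.filter_snr([mk(2.99)]) == []
        kept = proc.filter_snr([mk(3.0)])
        assert len(kept) == 1
        assert proc.filter_snr([]) == []


class TestPresenceFilter:
    @pytest.mark.parametrize("n_present,expected", [(4, False), (5, True), (10, True)])
    def test_boundary_at_half(self, n_present, expected):
        values = pd.DataFrame(
            {
                "A|[M+H]+|positive": [1.0] * n_present + [0.0] * (10 - n_present),
                "B|[M+H]+|positive": [1.0] * 10,
            },
            index=[f"s{i}" for i in range(10)],
        )
        out = proc.filter_presence(proc.LipidMatrix(values))
        assert ("A|[M+H]+|positive" in out.variable_ids) is expected

    def test_rejects_normalized_input(self):
        m = proc.LipidMatrix(pd.DataFrame({"a": [1.0]}), normalized=True)
        with pytest.raises(ValueError):
            proc.filter_presence(m)


class TestQcLinearityFilter:
    def run(self, qc_values, r_min=0.75):
        values = pd.DataFrame({"v": [1.0, 2.0]}, index=["s1", "s2"])
        qc = pd.DataFrame({"v": qc_values}, index=["QC1", "QC2", "QC3"])
        dil = {"QC1": 0.25, "QC2": 0.5, "QC3": 1.0}
        return proc.qc_linearity_filter(proc.LipidMatrix(values), qc, dil, r_min)

    def test_proportional_series_retained(self):
        out = self.run([25.0, 50.0, 100.0])
        assert out.variable_ids == ["v"]
        assert out.filter_log_frame().iloc[0]["statistic"] == pytest.approx(1.0)

    def test_constant_series_removed(self):
        out = self.run([100.0, 100.0, 100.0])
        assert out.variable_ids == []
        assert np.isnan(out.filter_log_frame().iloc[0]["statistic"])

    def test_anticorrelated_series_removed(self):
        out = self.run([100.0, 60.0, 25.0])
        assert out.variable_ids == []
        assert out.filter_log_frame().iloc[0]["statistic"] < 0

    def test_missing_manifest_is_hard_error(self):
        values = pd.DataFrame({"v": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="manifest"):
            proc.qc_linearity_filter(
                proc.LipidMatrix(values), pd.DataFrame({"v": []}), {}
            )

    def test_single_dilution_level_is_hard_error(self):
        values = pd.DataFrame({"v": [1.0]}, index=["s1"])
        qc = pd.DataFrame({"v": [10.0, 11.0]}, index=["QC1", "QC2"])
        with pytest.raises(ValueError, match="dilution levels"):
            proc.qc_linearity_filter(
                proc.LipidMatrix(values), qc, {"QC1": 0.5, "QC2": 0.5}
            )


class TestNormalization:
    def test_row_values(self):
        values = pd.DataFrame([[2.0, 3.0, 5.0]], columns=list("abc"), index=["s"])
        out = proc.normalize_per_mille(proc.LipidMatrix(values))
        assert out.values.loc["s"].tolist() == [200.0, 300.0, 500.0]
        assert out.normalized

    def test_single_variable_identity(self):
        values = pd.DataFrame({"a": [7.0, 3.0]}, index=["s1", "s2"])
        out = proc.normalize_per_mille(proc.LipidMatrix(values))
        assert (out.values["a"] == 1000.0).all()

    def test_rows_sum_to_thousand(self, tiny_matrix):
        sums = tiny_matrix.values.sum(axis=1)
        assert np.allclose(sums, 1000.0, rtol=1e-6)

    def test_idempotent(self, tiny_matrix):
        again = proc.normalize_per_mille(tiny_matrix)
        assert np.allclose(
            again.values.to_numpy(), tiny_matrix.values.to_numpy(), rtol=1e-9
        )

    def test_all_zero_row_error_names_sample(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [0.0, 0.0]], columns=["a", "b"], index=["good", "dead"]
        )
        with pytest.raises(ValueError, match="dead"):
            proc.normalize_per_mille(proc.LipidMatrix(values))

    def test_subset_after_normalization_warns(self, tiny_matrix):
        with pytest.warns(UserWarning, match="re-run"):
            tiny_matrix.subset_variables(tiny_matrix.variable_ids[:3])


class TestReclassifyDg:
    def test_dg_tagged_tg_untouched(self):
        values = pd.DataFrame(
            [[1.0, 2.0]],
            columns=["DG(32:0)|[M+NH4]+|positive", "TG(48:0)|[M+NH4]+|positive"],
            index=["s"],
        )
        out = proc.reclassify_dg(proc.LipidMatrix(values))
        assert out.var_tags["DG(32:0)|[M+NH4]+|positive"] == proc.TG_FRAGMENT_TAG
        assert "TG(48:0)|[M+NH4]+|positive" not in out.var_tags
        pd.testing.assert_frame_equal(out.values, values)

    def test_no_dg_matrix_unchanged(self):
        values = pd.DataFrame([[1.0]], columns=["PC(34:1)|[M+H]+|positive"], index=["s"])
        out = proc.reclassify_dg(proc.LipidMatrix(values))
        assert out.var_tags == {}


class TestFilterProperties:
    def test_relaxing_thresholds_is_monotone(self, tiny_peaklists, tiny_masslists):
        samples, qcs = tiny_peaklists
        pls = samples + qcs
        base = set(
            proc.process_peaklists(pls, tiny_masslists).variable_ids
        )
        for kwargs in (
            {"tol_ppm": 12.0},
            {"min_snr": 1.0},
            {"min_presence": 0.2},
            {"qc_r": 0.3},
        ):
            relaxed = set(
                proc.process_peaklists(pls, tiny_masslists, **kwargs).variable_ids
            )
            assert base <= relaxed, kwargs

    def test_sample_order_independence(self, tiny_peaklists, tiny_masslists):
        samples, qcs = tiny_peaklists
        fwd = proc.process_peaklists(samples + qcs, tiny_masslists)
        rev = proc.process_peaklists(list(reversed(samples + qcs)), tiny_masslists)
        assert fwd.variable_ids == rev.variable_ids
        pd.testing.assert_frame_equal(fwd.values, rev.values)

    def test_missing_qc_lists_fail_by_default(self, tiny_peaklists, tiny_masslists):
        samples, _ = tiny_peaklists
        with pytest.raises(ValueError, match="QC"):
            proc.process_peaklists(samples, tiny_masslists)


class TestPeaklistIO:
    def test_three_row_csv(self, tmp_path):
        p = tmp_path / "s1_pos.csv"
        p.write_text("800.1,100\n850.2,50\n900.3,10\n")
        pl = proc.read_peaklist_csv(p)
        assert (pl.sample_id, pl.polarity, len(pl)) == ("s1", "positive", 3)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "s1_neg.csv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            pl = proc.read_peaklist_csv(p)
        assert len(pl) == 0 and pl.polarity == "negative"

    def test_unsorted_csv_sorted_with_warning(self, tmp_path):
        p = tmp_path / "s1_pos.csv"
        p.write_text("900.3,10\n800.1,100\n")
        with pytest.warns(UserWarning, match="unsorted"):
            pl = proc.read_peaklist_csv(p)
        assert pl.mz.tolist() == [800.1, 900.3]

    def test_csv_round_trip_with_noise_column(self, tmp_path):
        pl = proc.PeakList(
            "s2", "negative", np.array([200.0, 300.0]), np.array([5.0, 6.0]),
            noise_level=2.5,
        )
        path = tmp_path / "s2_neg.csv"
        proc.write_peaklist_csv(pl, path)
        back = proc.read_peaklist_csv(path)
        assert np.allclose(back.mz, pl.mz)
        assert back.noise_level == pytest.approx(2.5)

    def test_mzml_round_trip(self, tmp_path):
        pls = [
            proc.PeakList("a", "positive", np.array([200.0, 500.5]),
                          np.array([10.0, 20.0]), noise_level=2.0),
            proc.PeakList("QC01", "negative", np.array([300.0]), np.array([7.0]),
                          noise_level=1.5, is_qc=True, qc_dilution=0.25),
        ]
        path = tmp_path / "x.mzML"
        proc.write_mzml(pls, path)
        back = proc.read_mzml(path)
        for orig, rt in zip(pls, back):
            assert orig.sample_id == rt.sample_id
            assert orig.polarity == rt.polarity
            assert np.array_equal(orig.mz, rt.mz)
            assert np.array_equal(orig.intensity, rt.intensity)
            assert orig.noise_level == rt.noise_level
            assert orig.qc_dilution == rt.qc_dilution

    def test_profile_mode_mzml_rejected(self, tmp_path):
        text = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<run id="r"><spectrumList count="1">
<spectrum index="0" id="sample=s" defaultArrayLength="0">
<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum"/>
<cvParam cvRef="MS" accession="MS:1000130" name="positive scan"/>
</spectrum></spectrumList></run></mzML>"""
        p = tmp_path / "profile.mzML"
        p.write_text(text)
        with pytest.raises(ValueError, match="profile-mode"):
            proc.read_mzml(p)

    def test_read_peaklists_applies_qc_manifest(self, tmp_path):
        (tmp_path / "s1_pos.csv").write_text("700.0,10\n")
        (tmp_path / "QC1_pos.csv").write_text("700.0,10\n")
        pls = proc.read_peaklists(
            sorted(tmp_path.iterdir()), qc_manifest={"QC1": 0.5}
        )
        by_id = {pl.sample_id: pl for pl in pls}
        assert by_id["QC1"].is_qc and by_id["QC1"].qc_dilution == 0.5
        assert not by_id["s1"].is_qc
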