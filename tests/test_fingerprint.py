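"""Peak detection, alignment, RPA fingerprints and similarity values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chansuqc.fingerprint import (
    AlignedPeakMatrix,
    Chromatogram,
    FingerprintVector,
    Peak,
    PeakTable,
    align_peaks,
    detect_peaks,
    reference_fingerprint,
    rrt_rpa,
    select_characteristic_peaks,
    similarity,
    similarity_report,
    validation_rsd,
)


def _gaussian_chrom(areas_rts, sigma=0.2, noise=0.0, seed=0, t_max=90.0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max, 0.01)
    y = np.zeros_like(t)
    for area, rt in areas_rts:
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    if noise:
        y += rng.normal(0, noise, t.shape)
    return Chromatogram(t, y)


class TestDetectPeaks:
    def test_single_peak_area_within_one_percent(self):
        tab = detect_peaks(_gaussian_chrom([(100.0, 45.0)]), 1.0, 1.0)
        assert len(tab.peaks) == 1
        assert tab.peaks[0].area == pytest.approx(100.0, rel=0.01)
        assert tab.peaks[0].rt == pytest.approx(45.0, abs=0.02)

    def test_flat_baseline_gives_empty_table(self):
        t = np.arange(0, 90, 0.01)
        tab = detect_peaks(Chromatogram(t, np.zeros_like(t)), 1.0, 1.0)
        assert tab.peaks == []

    def test_two_separated_peaks_recovered(self):
        tab = detect_peaks(_gaussian_chrom([(50.0, 30.0), (80.0, 60.0)]), 1.0, 1.0)
        assert len(tab.peaks) == 2
        assert tab.peaks[0].area == pytest.approx(50.0, rel=0.01)
        assert tab.peaks[1].area == pytest.approx(80.0, rel=0.01)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(Chromatogram(np.array([0.0, 1.0]), np.array([0.0, 1.0])))


def _table(rts_areas, batch=""):
    return PeakTable([Peak(rt, a, a) for rt, a in rts_areas], batch_id=batch)


class TestAlignPeaks:
    def test_identical_tables_fully_matched(self):
        tabs = [_table([(10.0, 5.0), (20.0, 7.0)], f"S{i}") for i in range(3)]
        m = align_peaks(tabs)
        assert m.areas.shape == (3, 2)
        assert (m.areas.values > 0).all()

    def test_small_jitter_still_fully_matched(self, rng):
        base = [10.0, 20.0, 30.0]
        tabs = [
            _table([(rt + rng.uniform(-0.2, 0.2), 5.0) for rt in base], f"S{i}")
            for i in range(4)
        ]
        m = align_peaks(tabs, rt_tol=0.5)
        assert m.areas.shape == (4, 3)
        assert (m.areas.values > 0).all()

    def test_missing_peak_leaves_zero_cell(self):
        tabs = [_table([(10.0, 5.0), (20.0, 7.0)], "a"), _table([(10.0, 5.0)], "b")]
        m = align_peaks(tabs)
        assert m.areas.loc["b"].min() == 0.0


class TestCharacteristicPeaks:
    def test_three_large_shared_peaks_carry_threshold(self):
        areas = pd.DataFrame(
            {
                "FP01": [40.0] * 5,
                "FP02": [30.0] * 5,
                "FP03": [22.0] * 5,
                "FP04": [4.0] * 5,
                "FP05": [4.0] * 5,
            }
        )
        m = AlignedPeakMatrix(areas, pd.Series([1, 2, 3, 4, 5.0], index=areas.columns))
        chosen, frac = select_characteristic_peaks(m, 0.90)
        assert chosen == ["FP01", "FP02", "FP03"]
        assert frac == pytest.approx(0.92)

    def test_peak_absent_in_one_sample_never_selected(self):
        areas = pd.DataFrame({"FP01": [100.0, 100.0], "FP02": [50.0, 0.0]})
        m = AlignedPeakMatrix(areas, pd.Series([1.0, 2.0], index=areas.columns))
        chosen, _ = select_characteristic_peaks(m, 0.90)
        assert "FP02" not in chosen

    def test_zero_threshold_selects_single_largest(self):
        areas = pd.DataFrame({"FP01": [10.0, 10.0], "FP02": [90.0, 90.0]})
        m = AlignedPeakMatrix(areas, pd.Series([1.0, 2.0], index=areas.columns))
        chosen, _ = select_characteristic_peaks(m, 0.0)
        assert chosen == ["FP02"]


class TestRrtRpa:
    def test_reference_peak_maps_to_unity(self):
        tab = rrt_rpa({"a": 5.0, "ref": 10.0}, {"a": 20.0, "ref": 40.0}, "ref")
        assert tab.loc["ref", "RRT"] == 1.0
        assert tab.loc["ref", "RPA"] == 1.0
        assert tab.loc["a", "RRT"] == 0.5
        assert tab.loc["a", "RPA"] == 0.5

    def test_rpa_invariant_to_common_area_rescale(self):
        a = rrt_rpa({"a": 5.0, "ref": 10.0}, {"a": 1.0, "ref": 2.0}, "ref")
        b = rrt_rpa({"a": 50.0, "ref": 100.0}, {"a": 1.0, "ref": 2.0}, "ref")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            rrt_rpa({"a": 5.0}, {"a": 1.0}, "ref")


def _fv(values, ref="p1", sample_id=""):
    return FingerprintVector(pd.Series(values), ref, sample_id)


class TestReferenceFingerprintAndSimilarity:
    def test_median_of_identical_vectors_is_identity(self):
        vs = [_fv({"p1": 1.0, "p2": 3.0}, sample_id=f"s{i}") for i in range(3)]
        ref = reference_fingerprint(vs)
        assert ref.values.equals(vs[0].values)

    def test_componentwise_median(self):
        vs = [
            _fv({"p1": 1.0, "p2": v}, sample_id=f"s{v}") for v in (1.0, 2.0, 10.0)
        ]
        assert reference_fingerprint(vs).values["p2"] == 2.0

    def test_median_order_invariant(self):
        vs = [_fv({"p1": 1.0, "p2": v}, sample_id=f"s{v}") for v in (4.0, 1.0, 9.0)]
        a = reference_fingerprint(vs).values
        b = reference_fingerprint(vs[::-1]).values
        assert a.equals(b)

    def test_self_similarity_is_one(self):
        v = _fv({"p1": 1.0, "p2": 2.0, "p3": 0.5})
        assert similarity(v, v) == pytest.approx(1.0)

    def test_hand_computed_cosine(self):
        a = _fv({"p1": 1.0, "p2": 0.0, "p3": 1.0})
        b = _fv({"p1": 1.0, "p2": 1.0, "p3": 1.0})
        assert similarity(a, b) == pytest.approx(2 / np.sqrt(6), abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_cosine_invariant_to_positive_rescale(self, k):
        # rescaling the non-reference components models a concentration shift
        a = _fv({"p1": 1.0, "p2": 2.0, "p3": 5.0})
        ref = _fv({"p1": 1.0, "p2": 1.5, "p3": 4.0})
        scaled = FingerprintVector(a.values * k / (a.values * k)["p1"], "p1")
        assert similarity(scaled, ref) == pytest.approx(similarity(a, ref), abs=1e-12)


class TestValidationRsd:
    def test_identical_replicates_zero_rsd(self):
        areas = [pd.Series({"a": 5.0, "ref": 10.0})] * 3
        rts = [pd.Series({"a": 20.0, "ref": 40.0})] * 3
        out = validation_rsd(areas, rts, "ref")
        assert (out.values == 0).all()

    def test_one_percent_noise_keeps_rsd_under_three_percent(self, rng):
        base = pd.Series({"a": 50.0, "b": 120.0, "ref": 200.0})
        rts = pd.Series({"a": 10.0, "b": 30.0, "ref": 42.5})
        areas = [base * (1 + rng.normal(0, 0.01, 3)) for _ in range(6)]
        out = validation_rsd(areas, [rts] * 6, "ref")
        assert out["RPA_rsd_pct"].max() < 3.0

    def test_rsd_invariant_to_common_rescale(self, rng):
        base = pd.Series({"a": 50.0, "ref": 200.0})
        rts = pd.Series({"a": 10.0, "ref": 42.5})
        noise = [1 + rng.normal(0, 0.02, 2) for _ in range(4)]
        a = validation_rsd([base * n for n in noise], [rts] * 4, "ref")
        b = validation_rsd([base * n * 7.5 for n in noise], [rts] * 4, "ref")
        pd.testing.assert_frame_equal(a, b)

    def test_two_replicates_required(self):
        with pytest.raises(ValueError):
            validation_rsd(
                [pd.Series({"ref": 1.0})], [pd.Series({"ref": 1.0})], "ref"
            )


class TestPipelineConsistency:
    def test_noiseless_rpa_equals_generating_ratios(self):
        """RPAs measured from noiseless synthetic chromatograms equal the
        generating area ratios within 1%."""
        gen = {"p1": 120.0, "p2": 260.0, "p3": 75.0}
        rts = {"p1": 20.0, "p2": 45.0, "p3": 70.0}
        chrom = _gaussian_chrom([(gen[k], rts[k]) for k in gen])
        tab = detect_peaks(chrom, 1.0, 1.0).to_frame()
        areas = {k: float(tab.loc[(tab["rt"] - rts[k]).abs().idxmin(), "area"]) for k in gen}
        got = rrt_rpa(areas, rts, "p2")["RPA"]
        want = pd.Series(gen, dtype=float) / gen["p2"]
        assert np.allclose(got.sort_index(), want.sort_index(), rtol=0.01)

    def test_within_origin_similarity_exceeds_between(self):
        """On the default five-origin synthetic study the mean within-origin
        SV exceeds the mean between-origin SV."""
        from chansuqc.simulate import SimulationConfig, generate_dataset

        ds = generate_dataset(SimulationConfig(seed=11))
        tables = [detect_peaks(c) for c in ds.chromatograms]
        aligned = align_peaks(tables)
        chosen, _ = select_characteristic_peaks(aligned)
        ref = max(chosen, key=lambda c: aligned.areas[c].mean())
        vectors = [
            FingerprintVector(
                rrt_rpa(aligned.areas.loc[s, chosen], aligned.consensus_rt[chosen], ref)["RPA"],
                ref, sample_id=s,
            )
            for s in aligned.areas.index
        ]
        origins = {s: str(ds.contents.origins[s]) for s in aligned.areas.index}
        rep = similarity_report(vectors, origins)
        assert rep.mean_within > rep.mean_between
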