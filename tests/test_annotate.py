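"""Fragmentation rule grammar, spectrum scoring and chemotype classification."""

import numpy as np
import pytest

from chansuqc.annotate import (
    FRAGMENT_TOLERANCE,
    PolarityModel,
    ProductIonSpectrum,
    annotate_spectrum,
    classify_spectrum,
    match_fragments,
    predict_fragments,
    rank_isomers,
)
from chansuqc.masses import MatchTolerance
from chansuqc.simulate import SimulationConfig, simulate_spectrum


def _rec(db, rid):
    return next(r for r in db if r.id == rid)


def _closest(frags, target):
    return min(abs(f.mz - target) for f in frags)


class TestPredictFragments:
    def test_bufalin_dehydration_ladder_and_pyrone(self, db):
        """The printed bufalin ions: -H2O, -2H2O, then alpha-pyrone loss."""
        frags = predict_fragments(_rec(db, "bufalin"))
        for printed in (387.2513, 369.2414, 351.2305, 255.2096):
            assert _closest(frags, printed) < FRAGMENT_TOLERANCE.window(printed)

    def test_suberoyl_arginine_series(self, db):
        """Diacid-conjugated arginine shows the full arginine ion series."""
        frags = predict_fragments(_rec(db, "suberoyl_arginine"))
        for printed in (331.1965, 175.1179, 158.0917, 112.0870, 70.0674):
            assert _closest(frags, printed) < FRAGMENT_TOLERANCE.window(printed)

    def test_serotonin_side_chain_loss(self, db):
        frags = predict_fragments(_rec(db, "serotonin"))
        assert _closest(frags, 160.0757) < 1e-3

    def test_bufalitoxin_regenerates_aglycone_and_moiety_ions(self, db):
        frags = predict_fragments(_rec(db, "bufalitoxin"), db=db)
        for printed in (699.4302, 681.4192, 387.2513, 331.1963):
            assert _closest(frags, printed) < FRAGMENT_TOLERANCE.window(printed)

    def test_substituent_specific_losses(self, db):
        # 19-CHO loses CO, 16-OAc loses acetic acid
        helle = predict_fragments(_rec(db, "hellebrigenin"))
        assert any("-CO]" in f.label for f in helle)
        cbg = predict_fragments(_rec(db, "cinobufagin"))
        assert any("-HOAc" in f.label for f in cbg)


class TestMatchFragments:
    def test_within_ten_ppm_matches(self, db):
        preds = predict_fragments(_rec(db, "bufalin"))
        spec = ProductIonSpectrum(387.2513, peaks=[(351.2305, 100.0)])
        matched = match_fragments(preds, spec)
        assert len(matched) == 1
        assert matched[0].predicted.label == "[M+H-2H2O]+"

    def test_empty_spectrum_no_matches(self, db):
        preds = predict_fragments(_rec(db, "bufalin"))
        assert match_fragments(preds, ProductIonSpectrum(387.25)) == []

    def test_each_observed_peak_used_once(self):
        from chansuqc.annotate import PredictedFragment

        preds = [
            PredictedFragment(351.2318, "a", "x"),
            PredictedFragment(351.2319, "b", "x"),
        ]
        spec = ProductIonSpectrum(400.0, peaks=[(351.2310, 10.0)])
        assert len(match_fragments(preds, spec)) == 1


class TestAnnotateSpectrum:
    def test_noiseless_forward_simulation_is_recovered_exactly(self, db):
        cfg = SimulationConfig(seed=0, ppm_jitter=0.0, decoy_peaks=0)
        rec = _rec(db, "bufalin")
        spec = simulate_spectrum(rec, cfg, db=db)
        results = annotate_spectrum(spec, db)
        assert results[0].record.id == "bufalin"
        assert results[0].fragment_score == 1.0

    def test_bufotoxin_identified_from_printed_ions(self, db):
        spec = ProductIonSpectrum(
            699.4302,
            peaks=[(681.4192, 80.0), (331.1963, 70.0), (387.2513, 60.0)],
        )
        results = annotate_spectrum(spec, db)
        assert results[0].record.id == "bufalitoxin"

    def test_precursor_outside_database_gives_empty(self, db):
        spec = ProductIonSpectrum(999.9999, peaks=[(160.0757, 10.0)])
        assert annotate_spectrum(spec, db) == []

    def test_round_trip_recovery_under_jitter_and_decoys(self, db):
        """Every fixture compound is top-ranked from its own simulated
        spectrum at +/-3 ppm jitter with 5 decoy peaks."""
        cfg = SimulationConfig(seed=0, ppm_jitter=3.0, decoy_peaks=5)
        rng = np.random.default_rng(2024)
        for rec in db:
            spec = simulate_spectrum(rec, cfg, db=db, rng=rng)
            results = annotate_spectrum(spec, db)
            assert results and results[0].record.id == rec.id, rec.id

    def test_fragment_subscore_monotone_in_matched_peaks(self, db):
        cfg = SimulationConfig(seed=3, ppm_jitter=0.0, decoy_peaks=0)
        spec = simulate_spectrum(_rec(db, "gamabufotalin"), cfg, db=db)
        full = annotate_spectrum(spec, db)[0]
        # drop one real fragment peak (not the precursor)
        reduced = ProductIonSpectrum(spec.precursor_mz, peaks=spec.peaks[1:])
        less = next(
            r for r in annotate_spectrum(reduced, db) if r.record.id == "gamabufotalin"
        )
        assert less.fragment_score <= full.fragment_score

    def test_decoys_do_not_change_matched_fragments(self, db, rng):
        cfg = SimulationConfig(seed=3, ppm_jitter=0.0, decoy_peaks=0)
        spec = simulate_spectrum(_rec(db, "bufotalin"), cfg, db=db)
        base = annotate_spectrum(spec, db)[0]
        decoys = np.column_stack(
            [rng.uniform(60, 400, 8), np.full(8, 1.0)]
        )
        noisy = ProductIonSpectrum(
            spec.precursor_mz, peaks=np.vstack([spec.peaks, decoys])
        )
        after = next(
            r for r in annotate_spectrum(noisy, db) if r.record.id == "bufotalin"
        )
        assert {m.predicted.label for m in after.matches} >= {
            m.predicted.label for m in base.matches
        }
        assert after.fragment_score == base.fragment_score


class TestClassify:
    def test_alkaloid_by_indole_ion(self):
        spec = ProductIonSpectrum(177.1022, peaks=[(160.0757, 100.0)])
        assert classify_spectrum(spec).assigned == "alkaloid"

    def test_bufotoxin_by_moiety_loss(self):
        spec = ProductIonSpectrum(
            699.4302, peaks=[(331.1963, 70.0), (387.2513, 60.0)]
        )
        assert classify_spectrum(spec).assigned == "bufotoxin"

    def test_empty_spectrum_unknown(self):
        assert classify_spectrum(ProductIonSpectrum(500.0)).assigned == "unknown"

    def test_forward_simulations_classify_to_generating_class(self, db):
        cfg = SimulationConfig(seed=1, ppm_jitter=3.0, decoy_peaks=5)
        rng = np.random.default_rng(77)
        for rec in db:
            spec = simulate_spectrum(rec, cfg, db=db, rng=rng)
            assert classify_spectrum(spec).assigned == rec.cls, rec.id


class TestRankIsomers:
    def test_five_oh_elutes_before_sixteen_oh(self, db):
        """The 5-OH isomer is more polar and takes the earlier peak."""
        marino = _rec(db, "marinobufagin")
        desace = _rec(db, "desacetylcinobufagin")
        res = rank_isomers([desace, marino], [62.5, 70.0])
        assert res.resolved
        assignment = dict((r.id, rt) for r, rt in res.assignments)
        assert assignment["marinobufagin"] < assignment["desacetylcinobufagin"]

    def test_single_candidate_trivial(self, db):
        rec = _rec(db, "bufalin")
        res = rank_isomers([rec], [10.0])
        assert res.resolved and res.assignments == [(rec, 10.0)]

    def test_equal_polarity_flagged_unresolved(self, db):
        a = _rec(db, "cinobufagin")
        b = _rec(db, "epi_cinobufagin")
        res = rank_isomers([a, b], [80.0, 85.0])
        assert not res.resolved

    def test_count_mismatch_rejected(self, db):
        with pytest.raises(ValueError):
            rank_isomers([_rec(db, "bufalin")], [1.0, 2.0])

    def test_polarity_model_invariant(self):
        with pytest.raises(ValueError):
            PolarityModel(weights=(("5_OH", 1.0), ("16_OH", 2.0)))
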