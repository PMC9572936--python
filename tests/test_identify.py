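"""Identification: tolerance matching, point tallies, candidate selection."""

import numpy as np
import pytest

from milkscreen.compounds import load_default_db
from milkscreen.identify import (
    FeatureObservation,
    identification_points,
    identify,
    identify_compound,
    match_fragments,
    match_precursor,
    match_rt,
    select_candidate,
)
from milkscreen.simulate import NoiseModel, gen_blank_run, gen_spiked_run

from conftest import brute_force_identify, make_compound


def feat(mz, rt, response=1000.0, frags=()):
    return FeatureObservation(mz=mz, rt_min=rt, response=response,
                              fragment_mzs=tuple(frags))


class TestMatchPrecursor:
    def test_exact_match(self, db):
        amox = db["Amoxicillin"]
        ok, err = match_precursor(feat(366.1118, 7.22), amox)
        assert ok and err == pytest.approx(0.0, abs=0.05)

    def test_ten_ppm_off_rejected(self, db):
        ok, err = match_precursor(feat(366.1155, 7.22), db["Amoxicillin"])
        assert not ok and err == pytest.approx(10.1, abs=0.2)

    def test_boundary_five_ppm_inclusive(self, db):
        import math

        amox = db["Amoxicillin"]
        # one ulp inside the +5 ppm boundary: flag must stay true (<=, not <)
        at_bound = math.nextafter(amox.precursor_mz * (1 + 5e-6), 0.0)
        ok, err = match_precursor(feat(at_bound, 7.22), amox)
        assert ok and err == pytest.approx(5.0, abs=1e-6)
        just_out = amox.precursor_mz * (1 + 5.01e-6)
        assert not match_precursor(feat(just_out, 7.22), amox)[0]


class TestMatchRt:
    @pytest.mark.parametrize(
        "observed, expected, ok, dev",
        [
            (7.22, 7.22, True, 0.0),
            (7.40, 7.22, True, 0.0249),
            (7.45, 7.22, False, 0.0319),
        ],
    )
    def test_window(self, observed, expected, ok, dev):
        got_ok, got_dev = match_rt(observed, expected)
        assert got_ok is ok
        assert got_dev == pytest.approx(dev, abs=1e-3)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            match_rt(5.0, 0.0)


class TestMatchFragments:
    def test_both_tabulated_fragments(self, db):
        assert match_fragments([208.0, 349.1], db["Amoxicillin"]) == 2

    def test_empty_observation(self, db):
        assert match_fragments([], db["Amoxicillin"]) == 0

    def test_within_absolute_tolerance(self, db):
        assert match_fragments([208.04], db["Amoxicillin"]) == 1

    def test_one_observation_consumed_once(self):
        comp = make_compound(fragments=(208.0, 208.05))
        # one observed ion equidistant-ish from both tabulated values may
        # satisfy only one of them
        assert match_fragments([208.02], comp) == 1


class TestPointTally:
    @pytest.mark.parametrize(
        "rt, prec, nfrag, points",
        [
            (True, True, 2, 7.5),
            (True, True, 1, 5.0),
            (True, False, 0, 1.0),
            (False, False, 0, 0.0),
            (False, True, 2, 6.5),
        ],
    )
    def test_tally(self, rt, prec, nfrag, points):
        assert identification_points(rt, prec, nfrag) == points

    def test_negative_fragments_rejected(self):
        with pytest.raises(ValueError):
            identification_points(True, True, -1)

    def test_adding_a_fragment_never_decreases_points(self):
        for nfrag in range(5):
            assert identification_points(True, True, nfrag + 1) > \
                identification_points(True, True, nfrag)


class TestIdentifyCompound:
    def test_full_evidence_authorized(self, db):
        amox = db["Amoxicillin"]
        res = identify_compound([feat(366.1118, 7.22, frags=(208.0, 349.1))],
                                amox)
        assert res.identified and res.points == 7.5 and res.required_points == 4.0

    def test_one_fragment_still_identifies_either_status(self, db):
        # 1.0 + 1.5 + 2.5 = 5.0 points: enough for authorized (>=4) and
        # unauthorized (>=5) alike
        amox = db["Amoxicillin"]           # authorized
        tiam = db["Tiamulin"]              # unauthorized
        res_a = identify_compound([feat(amox.precursor_mz, 7.22,
                                        frags=(208.0,))], amox)
        res_u = identify_compound([feat(tiam.precursor_mz, 15.70,
                                        frags=(192.1,))], tiam)
        assert res_a.points == res_u.points == 5.0
        assert res_a.identified and res_u.identified
        assert res_u.required_points == 5.0

    def test_no_fragments_fails_even_with_precursor_and_rt(self, db):
        res = identify_compound([feat(366.1118, 7.22)], db["Amoxicillin"])
        assert res.points == 2.5 and not res.identified

    def test_rt_point_needs_precursor_company(self, db):
        # a feature at the right RT but the wrong mass matches nothing
        res = identify_compound([feat(400.0, 7.22)], db["Amoxicillin"])
        assert res.points == 0.0 and res.feature is None

    def test_absence_is_not_an_error(self, db):
        results = identify([], db)
        assert len(results) == 57
        assert not any(r.identified for r in results.values())


class TestCandidateSelection:
    def test_in_window_fragment_bearing_peak_beats_interference(self, db):
        amox = db["Amoxicillin"]
        spike = feat(amox.precursor_mz * (1 + 3e-6), 7.25, 50000.0,
                     (208.0, 349.1))
        interference = feat(amox.precursor_mz * (1 + 1e-6), 7.30, 20.0)
        assert select_candidate([interference, spike], amox) is spike

    def test_out_of_window_peak_ranked_by_ppm_only(self, db):
        amox = db["Amoxicillin"]
        far = feat(amox.precursor_mz, 9.0, 9e9)     # outside RT window
        near = feat(amox.precursor_mz * (1 + 4e-6), 7.22, 10.0)
        assert select_candidate([far, near], amox) is near

    def test_epimer_peak_with_own_fragments_does_not_steal(self, db):
        # doxycycline and its epimer share C22H24N2O8; a big epimer peak
        # drifting into doxycycline's RT window must not outrank the true,
        # fragment-confirmed doxycycline peak
        doxy = db["Doxycycline"]
        true_peak = feat(doxy.precursor_mz, 14.25, 50000.0, (428.1, 410.1))
        epimer = feat(doxy.precursor_mz, 13.92, 150000.0, (428.1,))
        assert select_candidate([epimer, true_peak], doxy) is true_peak


class TestPipelineIdentification:
    def test_zero_noise_spiked_run_scores_full_points(self, db):
        noise = NoiseModel(mass_error_sd_ppm=0.0, rt_jitter_sd_frac=0.0,
                           blank_false_rate=0.0)
        run = gen_spiked_run(db, db.stc_table(), noise, seed=5)
        results = identify(run, db)
        assert all(r.identified and r.points == 7.5 for r in results.values())

    def test_clean_blank_identifies_nothing(self, db):
        noise = NoiseModel(blank_false_rate=0.0)
        run = gen_blank_run(db, noise, seed=5)
        results = identify(run, db)
        assert not any(r.identified for r in results.values())

    def test_noisy_spiked_run_still_hits_every_target(self, db):
        # mass/RT errors are truncated at the tolerances, so identification
        # of true spikes cannot fail on tolerance grounds
        run = gen_spiked_run(db, db.stc_table(), NoiseModel(), seed=11)
        results = identify(run, db)
        assert all(r.identified for r in results.values())

    def test_widening_tolerances_never_shrinks_identified_set(self, db):
        run = gen_spiked_run(db, db.stc_table(), NoiseModel(), seed=3)
        narrow = {n for n, r in identify(run, db, ppm_tol=2.0,
                                         rt_tol_frac=0.01).items()
                  if r.identified}
        wide = {n for n, r in identify(run, db, ppm_tol=5.0,
                                       rt_tol_frac=0.025).items()
                if r.identified}
        assert narrow <= wide


class TestBruteForceOracle:
    def test_agrees_on_small_random_instances(self, db):
        rng = np.random.default_rng(2024)
        small_db = db.subset(["Amoxicillin", "Tetracycline", "Doxycycline",
                              "Tylosin", "Lincomycin"])
        for _ in range(60):
            features = []
            for _ in range(rng.integers(0, 6)):
                comp = small_db.compounds[rng.integers(0, 5)]
                mz = comp.precursor_mz * (1 + rng.uniform(-8e-6, 8e-6))
                rt = comp.expected_rt * (1 + rng.uniform(-0.05, 0.05))
                nf = rng.integers(0, 3)
                frags = tuple(
                    f + rng.uniform(-0.08, 0.08)
                    for f in comp.fragment_mzs[: int(nf)]
                )
                features.append(feat(mz, rt, float(rng.uniform(10, 1e5)),
                                     frags))
            mine = identify(features, small_db)
            reference = brute_force_identify(features, small_db)
            for name in small_db.names():
                ref_feat, ref_points, ref_ident = reference[name]
                assert mine[name].feature is ref_feat, name
                assert mine[name].points == ref_points, name
                assert mine[name].identified == ref_ident, name
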