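"""Wave classification, duration threshold, TOSS encoding."""

import numpy as np
import pytest

from snailrelay import StimulusProfile, Trajectory, simulate
from snailrelay.duration import (ClassificationError, classify_waves,
                                 duration_scan, duration_threshold,
                                 encode_toss, modulation_report)


def synthetic_traj(fold_fn, species=("SNAIL1_prot",), t_max=72.0):
    t = np.arange(0.0, t_max + 0.05, 0.1)
    cols = np.column_stack([np.asarray([fold_fn(x) for x in t]) for _ in species])
    return Trajectory(t, tuple(species), cols, np.ones(len(species)),
                      StimulusProfile())


class TestClassifyWaves:
    def test_flat_trajectory_is_none(self):
        traj = synthetic_traj(lambda t: 1.0)
        assert classify_waves(traj).label == "none"

    def test_single_transient_is_one_wave(self):
        traj = synthetic_traj(lambda t: 1.0 + 3.0 * np.exp(-((t - 14) / 6) ** 2))
        c = classify_waves(traj)
        assert c.label == "one_wave"
        assert c.peak_times[0] == pytest.approx(14.0, abs=0.5)

    def test_small_bump_below_threshold_is_none(self):
        traj = synthetic_traj(lambda t: 1.0 + 0.3 * np.exp(-((t - 14) / 6) ** 2))
        assert classify_waves(traj).label == "none"

    def test_peak_dip_sustained_rise_is_two_wave(self):
        traj = synthetic_traj(
            lambda t: 1.0 + 3.0 * np.exp(-((t - 14) / 5) ** 2)
            + 5.0 / (1.0 + np.exp(-(t - 40) / 6)))
        c = classify_waves(traj)
        assert c.label == "two_wave"
        assert c.level_72h > 1.5

    def test_transient_second_bump_without_sustained_level_not_two_wave(self):
        traj = synthetic_traj(
            lambda t: 1.0 + 3.0 * np.exp(-((t - 14) / 5) ** 2)
            + 3.0 * np.exp(-((t - 44) / 5) ** 2))
        assert classify_waves(traj).label != "two_wave"

    def test_short_horizon_rejected(self):
        traj = synthetic_traj(lambda t: 1.0, t_max=48.0)
        with pytest.raises(ClassificationError, match="72"):
            classify_waves(traj)


class TestCalibratedClassification:
    def test_continuous_stimulus_is_two_wave(self, full_model, cal_params,
                                             cal_basal):
        traj = simulate(full_model, cal_params, StimulusProfile(),
                        t_max=72.0, basal=cal_basal)
        assert classify_waves(traj).label == "two_wave"

    def test_pulse_discrimination_2h_vs_8h(self, full_model, cal_params,
                                           cal_basal):
        t2 = simulate(full_model, cal_params, StimulusProfile.pulse(2.0),
                      t_max=72.0, basal=cal_basal)
        t8 = simulate(full_model, cal_params, StimulusProfile.pulse(8.0),
                      t_max=72.0, basal=cal_basal)
        assert classify_waves(t2).label == "one_wave"
        assert classify_waves(t8).label == "two_wave"

    def test_duration_scan_labels_and_monotone_commitment(self, full_model,
                                                          cal_params, cal_basal):
        """Labels go none -> one_wave -> two_wave with duration up to 12 h;
        very long pulses may merge the waves (the scan would then warn), but
        the sustained 72-h commitment itself stays monotone."""
        scan = duration_scan(full_model, cal_params, (0, 1, 2, 4, 6, 8, 12),
                             basal=cal_basal, method="fast")
        order = {"none": 0, "one_wave": 1, "two_wave": 2}
        ranks = [order[l] for l in scan.labels]
        assert scan.labels[0] == "none"
        assert ranks == sorted(ranks)
        assert scan.labels[-1] == "two_wave"
        lvl72 = scan.snail1[:, -1]
        assert all(b >= a - 1e-9 for a, b in zip(lvl72, lvl72[1:]))


class TestDurationThreshold:
    def test_threshold_lies_inside_2_8_bracket(self, full_model, cal_params,
                                               cal_basal):
        thr = duration_threshold(full_model, cal_params, 2.0, 8.0,
                                 basal=cal_basal, method="fast")
        assert 2.0 < thr < 8.0

    def test_nuclear_gsk3_activity_raises_the_threshold(self, full_model,
                                                        cal_params, cal_basal):
        base = duration_threshold(full_model, cal_params, 0.25, 12.0,
                                  basal=cal_basal, method="fast")
        up = duration_threshold(full_model, cal_params.scaled({"m_nuc": 1.5}),
                                0.25, 12.0, method="fast")
        assert up > base

    def test_invalid_brackets_rejected(self, full_model, cal_params, cal_basal):
        with pytest.raises(ValueError, match="lo < hi"):
            duration_threshold(full_model, cal_params, 4.0, 4.0, basal=cal_basal)
        with pytest.raises(ValueError, match="bracket invalid"):
            duration_threshold(full_model, cal_params, 12.0, 48.0,
                               basal=cal_basal, method="fast")

    def test_bisection_deterministic(self, full_model, cal_params, cal_basal):
        a = duration_threshold(full_model, cal_params, 2.0, 8.0,
                               basal=cal_basal, method="fast")
        b = duration_threshold(full_model, cal_params, 2.0, 8.0,
                               basal=cal_basal, method="fast")
        assert a == b

    def test_identity_modulation_gives_zero_shift(self, full_model, cal_params):
        base = duration_threshold(full_model, cal_params, 0.5, 12.0,
                                  method="fast")
        same = duration_threshold(full_model,
                                  cal_params.scaled({"m_nuc": 1.0, "m_cyt": 1.0}),
                                  0.5, 12.0, method="fast")
        assert base == same


class TestToss:
    def test_synthetic_thresholds(self):
        traj = synthetic_traj(lambda t: 1.0,
                              species=("pSMAD_nuc", "GLI1_nuc", "SNAIL1_prot"))
        s = encode_toss(traj)
        assert s.psmad == ("L", "L") and s.gli1 == ("L", "L") and s.snail1 == ("L", "L")

    def test_short_horizon_rejected(self):
        traj = synthetic_traj(lambda t: 1.0, t_max=24.0,
                              species=("pSMAD_nuc", "GLI1_nuc", "SNAIL1_prot"))
        with pytest.raises(ClassificationError, match="48"):
            encode_toss(traj)

    def test_custom_thresholds_override_defaults(self):
        traj = synthetic_traj(lambda t: 2.0,
                              species=("pSMAD_nuc", "GLI1_nuc", "SNAIL1_prot"))
        hi = encode_toss(traj, {"psmad": (2.5, 4.0), "gli1": 2.5, "snail1": 2.5})
        lo = encode_toss(traj)
        assert hi.psmad == ("L", "L") and lo.psmad == ("M", "M")

    def test_canonical_states_of_the_three_stimuli(self, full_model, cal_params,
                                                   cal_basal):
        """No TGF-beta, 2 h pulse and 8 h pulse encode to the three canonical
        duration codes: (L,L;L,L), (H,L;L,L), (H,M;L,H) with SNAIL1
        (L,L), (H,L), (H,H)."""
        runs = {
            "none": StimulusProfile.zero(),
            "p2": StimulusProfile.pulse(2.0),
            "p8": StimulusProfile.pulse(8.0),
        }
        states = {k: encode_toss(simulate(full_model, cal_params, stim,
                                          t_max=72.0, basal=cal_basal))
                  for k, stim in runs.items()}
        assert states["none"].psmad == ("L", "L")
        assert states["none"].gli1 == ("L", "L")
        assert states["none"].snail1 == ("L", "L")
        assert states["p2"].psmad == ("H", "L")
        assert states["p2"].gli1 == ("L", "L")
        assert states["p2"].snail1 == ("H", "L")
        assert states["p8"].psmad == ("H", "M")
        assert states["p8"].gli1 == ("L", "H")
        assert states["p8"].snail1 == ("H", "H")
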