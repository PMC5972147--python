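"""Model construction, basal normalization, conservation and simulation."""

import numpy as np
import pytest

from snailrelay import (InhibitorSpec, ParameterSet, StimulusProfile,
                        build_model, simulate)
from snailrelay.models import NSTATE, VARIANTS, rhs_kernel
from snailrelay.simulate import SimulationError, basal_state
from snailrelay.stimulus import segment_table

from .conftest import random_in_bounds


class TestBuildModel:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            build_model("SMAD_PLUS")

    def test_smad_only_roster_and_params(self, smad_model):
        assert smad_model.species == ("pSMAD_nuc", "ISMAD", "SNAIL1_mRNA", "SNAIL1_prot")
        assert smad_model.n_species == 4
        # no GLI1 or GSK3 kinetic parameters in the variant's parameter list
        assert not any(p.startswith(("a_G", "K_G", "rho", "k_aa", "r_aa", "k_d", "r_d"))
                       or p in ("a_SG", "K_SG", "f_aa_b", "f_d_b", "lam_loc")
                       for p in smad_model.param_names)

    @pytest.mark.parametrize("inner,outer", [("SMAD_ONLY", "SMAD_GLI"),
                                             ("SMAD_GLI", "FULL")])
    def test_nesting_of_rosters(self, inner, outer):
        mi, mo = build_model(inner), build_model(outer)
        assert mi.species == mo.species[:mi.n_species]
        assert set(mi.param_names) <= set(mo.param_names)
        assert set(mi.edges) <= set(mo.edges)

    def test_full_contains_gli1_self_activation_edge(self, full_model):
        assert ("GLI1_nuc", "GLI1_mRNA", "+") in full_model.edges

    def test_full_reduces_to_smad_only_when_relay_edges_removed(
            self, full_model, smad_model, cal_params):
        """Zeroing the GSK3 conversions and GLI1 edges leaves, on the shared
        species, exactly the SMAD-only right-hand side."""
        p_red = cal_params.to_vector()
        from snailrelay.params import _INDEX
        for name in ("k_aa", "k_d", "a_SG", "b_G", "a_GR", "a_GG", "k_tg"):
            p_red[_INDEX[name]] = 1e-300
        rng = np.random.default_rng(0)
        fa, fd = cal_params["f_aa_b"], cal_params["f_d_b"]
        for _ in range(20):
            y = np.zeros(NSTATE)
            y[:4] = rng.uniform(0.01, 2.0, 4)     # shared species
            y[8], y[9] = fa, fd                   # GSK3 pinned at basal
            d_full = full_model.rhs(0.0, y, p_red, S=1.0)
            d_smad = smad_model.rhs(0.0, y, p_red, S=1.0)
            assert np.max(np.abs(d_full[:4] - d_smad[:4])) < 1e-12


class TestBasalState:
    def test_rhs_vanishes_at_basal(self, full_model, cal_params, cal_basal):
        res = full_model.rhs(0.0, cal_basal.state, cal_params, S=0.0)
        assert np.max(np.abs(res)) < 1e-8

    def test_zero_stimulus_holds_fold_change_at_one(self, full_model, cal_params,
                                                    cal_basal):
        traj = simulate(full_model, cal_params, StimulusProfile.zero(),
                        t_max=72.0, basal=cal_basal)
        assert np.max(np.abs(traj.fold - 1.0)) < 1e-4

    def test_basal_mrna_increases_with_its_synthesis_rate(self, full_model,
                                                          center_params):
        """Doubling basal SNAIL1 transcription raises basal SNAIL1 mRNA, across
        a spread of parameter sets (Latin-hypercube-like random draws)."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(25):
            ps = random_in_bounds(center_params, rng,
                                  names=("b_S", "d_Sm", "d_R", "k_I", "b_G"))
            try:
                lo = basal_state(full_model, ps)
                hi = basal_state(full_model, ps.scaled({"b_S": 2.0}))
            except SimulationError:
                continue
            i = full_model.species.index("SNAIL1_mRNA")
            assert hi.values[i] > lo.values[i]
            checked += 1
        assert checked >= 15


class TestSimulate:
    def test_fold_change_is_one_at_t0(self, full_model, cal_params, cal_basal):
        traj = simulate(full_model, cal_params, StimulusProfile(), t_max=24.0,
                        basal=cal_basal)
        assert np.max(np.abs(traj.fold[0] - 1.0)) < 1e-6

    def test_gsk3_conservation_along_trajectory(self, full_model, cal_params,
                                                cal_basal):
        traj = simulate(full_model, cal_params, StimulusProfile(), t_max=72.0,
                        basal=cal_basal)
        total = (traj.series("GSK3_A") * traj.basal[full_model.species.index("GSK3_A")]
                 + traj.series("GSK3_AA") * traj.basal[full_model.species.index("GSK3_AA")]
                 + traj.series("GSK3_D") * traj.basal[full_model.species.index("GSK3_D")])
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_psmad_transient_and_snail1_two_waves(self, full_model, cal_params,
                                                  cal_basal):
        """Continuous stimulus: nuclear pSMAD rises then falls; SNAIL1 protein
        shows an early wave, a dip, and a sustained second rise."""
        traj = simulate(full_model, cal_params, StimulusProfile(), t_max=72.0,
                        basal=cal_basal)
        r = traj.series("pSMAD_nuc")
        t_pk = traj.argmax_time("pSMAD_nuc")
        assert 6.0 < t_pk < 20.0
        assert traj.value("pSMAD_nuc", 48.0) < 0.6 * r.max()
        sp = traj.series("SNAIL1_prot")
        i_first = np.argmax(traj.times > 24.0)
        first_peak = sp[:i_first].max()
        dip = sp[i_first:].min()
        assert first_peak > 1.5
        assert dip < 0.95 * first_peak
        assert traj.value("SNAIL1_prot", 72.0) > max(1.5, dip * 1.25)

    def test_gsk3_aa_transient_peaks_then_returns(self, full_model, cal_params,
                                                  cal_basal):
        traj = simulate(full_model, cal_params, StimulusProfile(), t_max=24.0,
                        basal=cal_basal)
        t_pk = traj.argmax_time("GSK3_AA")
        assert 4.0 < t_pk < 10.0
        aa12 = traj.raw("GSK3_AA", 12.0)
        assert abs(aa12 - cal_params["f_aa_b"]) < 0.012

    def test_fast_and_strict_integrators_agree(self, full_model, cal_params,
                                               cal_basal):
        kw = dict(t_max=72.0, basal=cal_basal)
        a = simulate(full_model, cal_params, StimulusProfile.pulse(8.0),
                     [InhibitorSpec("GSK3_ACT", 24.0, 48.0)], method="strict", **kw)
        b = simulate(full_model, cal_params, StimulusProfile.pulse(8.0),
                     [InhibitorSpec("GSK3_ACT", 24.0, 48.0)], method="fast", **kw)
        assert np.max(np.abs(a.fold - b.fold)) < 1e-4

    def test_time_grid_outside_range_rejected(self, full_model, cal_params):
        with pytest.raises(ValueError, match="within"):
            simulate(full_model, cal_params, t_grid=np.array([0.0, 100.0, 300.0]))

    def test_monotone_peak_response_in_stimulus_amplitude(self, full_model,
                                                          cal_params, cal_basal):
        peaks = []
        for amp in (0.25, 0.5, 1.0, 2.0):
            traj = simulate(full_model, cal_params,
                            StimulusProfile(amplitude=amp), t_max=48.0,
                            basal=cal_basal)
            peaks.append(traj.series("pSMAD_nuc").max())
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))


class TestInhibitors:
    def test_zero_efficacy_is_identity(self, full_model, cal_params, cal_basal):
        ref = simulate(full_model, cal_params, StimulusProfile(), t_max=48.0,
                       basal=cal_basal)
        inh = simulate(full_model, cal_params, StimulusProfile(),
                       [InhibitorSpec("GSK3_ACT", 0.0, efficacy=0.0)],
                       t_max=48.0, basal=cal_basal)
        assert np.max(np.abs(ref.fold - inh.fold)) < 1e-10

    def test_full_smad_block_keeps_psmad_at_basal(self, full_model, cal_params,
                                                  cal_basal):
        traj = simulate(full_model, cal_params, StimulusProfile(),
                        [InhibitorSpec("SMAD_PHOS", 0.0, efficacy=1.0)],
                        t_max=72.0, basal=cal_basal)
        assert np.max(traj.series("pSMAD_nuc")) <= 1.0 + 1e-6

    def test_gsk3_inhibition_raises_snail1_without_moving_gli1(
            self, full_model, cal_params, cal_basal):
        """GSK3 inhibition without TGF-beta raises SNAIL1 protein but does not
        recapitulate GLI1 nuclear translocation."""
        traj = simulate(full_model, cal_params, StimulusProfile.zero(),
                        [InhibitorSpec("GSK3_ACT", 0.0)], t_max=72.0,
                        basal=cal_basal)
        assert traj.value("SNAIL1_prot", 24.0) > 1.0
        gn = traj.series("GLI1_nuc")
        assert np.max(np.abs(gn - 1.0)) <= 0.20

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown inhibitor target"):
            InhibitorSpec("WNT", 0.0)
        with pytest.raises(ValueError, match="efficacy"):
            InhibitorSpec("GSK3_ACT", 0.0, efficacy=1.5)
        with pytest.raises(ValueError, match="start < end"):
            InhibitorSpec("GSK3_ACT", 10.0, 10.0)


class TestStimulus:
    def test_segment_table_covers_interval(self):
        stim = StimulusProfile.pulse(8.0)
        inh = (InhibitorSpec("SMAD_PHOS", 48.0),)
        edges, vals = segment_table(stim, inh, 0.0, 72.0)
        assert edges[0] == 0.0 and edges[-1] == 72.0
        assert vals.shape == (len(edges) - 1, 4)
        # S on during [0,8), SMAD gate engaged from 48
        assert vals[0, 0] == 1.0 and vals[-1, 0] == 0.0
        assert vals[-1, 1] < 1.0

    def test_pulse_requires_duration(self):
        with pytest.raises(ValueError, match="duration"):
            StimulusProfile(kind="pulse")


class TestNonNegativityProperty:
    def test_random_parameter_sets_stay_nonnegative(self, full_model,
                                                    center_params):
        """Species never go measurably negative across random in-bounds
        parameter sets and random stimuli."""
        rng = np.random.default_rng(7)
        n_ok = 0
        for _ in range(200):
            ps = random_in_bounds(center_params, rng)
            amp = float(rng.uniform(0.2, 2.0))
            dur = float(rng.uniform(1.0, 48.0))
            stim = (StimulusProfile(amplitude=amp) if rng.random() < 0.5
                    else StimulusProfile.pulse(dur, amplitude=amp))
            try:
                traj = simulate(full_model, ps, stim, t_max=72.0, method="fast")
            except SimulationError:
                continue  # non-stationary sets are reported, not crashed on
            raw = traj.fold * traj.basal
            assert raw.min() >= -1e-9
            total = (traj.series("GSK3_A") * traj.basal[8]
                     + traj.series("GSK3_AA") * traj.basal[9]
                     + traj.series("GSK3_D") * traj.basal[10])
            assert np.max(np.abs(total - 1.0)) < 1e-9
            n_ok += 1
        assert n_ok >= 100
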