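import numpy as np
import pytest

from cartmac.macrophage_analysis import (
    activation_timeline,
    decompose_activation,
    single_mechanism_simulation,
)
from cartmac.model_core import CartTumorParams, CytokineParams, DoseRegimen, ModelState
from cartmac.simulation import observables, simulate
from cartmac.synthetic_data import cd40_dominant_archetype, generate_patient

from conftest import noiseless


class TestConservation:
    def test_subpopulations_sum_to_total(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pt = generate_patient("high_CRS", int(rng.integers(0, 1000)))
            traj = pt.true_trajectory(track_activation=True)
            dec = decompose_activation(traj)
            Ma = traj.column("M_a")
            total = dec.M_a1 + dec.M_a2 + dec.M_a3
            scale = max(float(np.max(Ma)), 1.0)
            assert np.max(np.abs(total - Ma)) / scale < 1e-4

    def test_fractions_sum_to_one(self, cd40_patient):
        dec = decompose_activation(
            cd40_patient.true_trajectory(track_activation=True))
        assert sum(dec.fractions.values()) == pytest.approx(1.0)


class TestDecomposition:
    def test_damp_only_when_other_mechanisms_off(self, reference_params):
        q = CytokineParams(sigma_M=1e8, delta_M=0.15, sigma_I=10, delta_I=2,
                           alpha=4e-8, beta_B=0.0, beta_K=1e-11, beta_C=0.0)
        init = ModelState(T_P=3e10, M_i=1e10, IL6=5.0)
        traj = simulate(reference_params, q, init, DoseRegimen.single(1e8),
                        horizon=60.0, track_activation=True)
        dec = decompose_activation(traj)
        assert np.all(dec.M_a2 == 0.0) and np.all(dec.M_a3 == 0.0)
        assert dec.fractions["DAMP"] == pytest.approx(1.0)

    def test_cumulative_integral_closed_form(self):
        # freeze the drivers: constant C_E and T_P, and constant M_i via a
        # production rate balancing activation + death -> J1 = h1*M_i0*tF
        p = CartTumorParams(eta=0.0, mu_I=0.0, kappa=0.0, mu_E=0.0,
                            epsilon=0.0, theta=0.0, mu_P=0.0, rho=0.0,
                            gamma=0.0, A=1e8, B=1e8)
        C_E, T_P, M_i0 = 1e8, 1e10, 1e9
        beta_K, delta_M = 3e-12, 0.2
        h1 = beta_K * (C_E / (p.B + C_E)) * T_P
        q = CytokineParams(sigma_M=(h1 + delta_M) * M_i0, delta_M=delta_M,
                           sigma_I=0.0, delta_I=1.0, alpha=0.0,
                           beta_B=0.0, beta_K=beta_K, beta_C=0.0)
        init = ModelState(C_E=C_E, T_P=T_P, M_i=M_i0)
        tF = 30.0
        traj = simulate(p, q, init, horizon=tF, track_activation=True)
        dec = decompose_activation(traj)
        assert dec.integrals["DAMP"] == pytest.approx(h1 * M_i0 * tF, rel=1e-5)

    def test_requires_tracked_trajectory(self, cd40_patient):
        traj = cd40_patient.true_trajectory(track_activation=False)
        with pytest.raises(ValueError, match="track_activation"):
            decompose_activation(traj)

    def test_cd40_dominance_and_ordering(self):
        arch = cd40_dominant_archetype()
        for seed in (0, 1, 3):
            pt = generate_patient(noiseless(arch), seed)
            dec = decompose_activation(
                pt.true_trajectory(track_activation=True))
            assert dec.fractions["CD40"] > 0.5
            assert (dec.peak_days["DAMP"] <= dec.peak_days["antigen"]
                    <= dec.peak_days["CD40"])


class TestTimeline:
    def test_event_ordering_table(self, cd40_patient):
        traj = cd40_patient.true_trajectory(track_activation=True)
        dec = decompose_activation(traj)
        tl = activation_timeline(dec, traj)
        days = tl.set_index("event")["day"]
        assert days["M_a(DAMP) peak"] <= days["M_a(CD40) peak"]
        assert "IL-6 peak" in days.index and "CAR-T peak" in days.index

    def test_inactive_mechanism_flagged(self, reference_params):
        q = CytokineParams(sigma_M=1e8, delta_M=0.15, sigma_I=10, delta_I=2,
                           alpha=4e-8, beta_B=1e-12, beta_K=1e-11, beta_C=0.0)
        init = ModelState(T_P=3e10, M_i=1e10, IL6=5.0)
        traj = simulate(reference_params, q, init, DoseRegimen.single(1e8),
                        horizon=60.0, track_activation=True)
        tl = activation_timeline(decompose_activation(traj), traj)
        row = tl[tl["event"] == "M_a(CD40) peak"].iloc[0]
        assert row["flag"] != ""

    def test_il6_peak_follows_macrophage_peak(self):
        for seed in range(4):
            pt = generate_patient(noiseless("high_CRS"), seed)
            obs = observables(pt.true_trajectory(), pt.extras["dose"])
            assert obs.il6_peak_day >= obs.macrophage_peak_day - 0.05


class TestSingleMechanism:
    def test_cd40_alone_stays_at_baseline(self, cd40_patient):
        pt = cd40_patient
        q = pt.cytokine
        init = ModelState(T_P=pt.init.T_P, M_i=pt.init.M_i,
                          IL6=q.sigma_I / q.delta_I)
        traj = single_mechanism_simulation(pt.params, q, init, pt.regimen,
                                           {"CD40"}, horizon=60.0)
        il6 = traj.column("IL6")
        assert np.allclose(il6, il6[0], rtol=1e-6)

    def test_full_subset_identical_to_full_simulation(self, cd40_patient):
        pt = cd40_patient
        a = single_mechanism_simulation(pt.params, pt.cytokine, pt.init,
                                        pt.regimen,
                                        {"DAMP", "antigen", "CD40"},
                                        horizon=60.0)
        b = simulate(pt.params, pt.cytokine, pt.init, pt.regimen, horizon=60.0)
        assert np.allclose(a.column("IL6"), b.column("IL6"), rtol=1e-10)

    def test_damp_only_peaks_during_tumor_shrinkage(self, cd40_patient):
        from cartmac.phase_analysis import segment_tumor_phases
        pt = cd40_patient
        traj = single_mechanism_simulation(pt.params, pt.cytokine, pt.init,
                                           pt.regimen, {"DAMP"}, horizon=90.0)
        seg = segment_tumor_phases(traj)
        il6 = traj.column("IL6")
        peak_day = traj.t[int(np.argmax(il6))]
        t0, t1 = seg.shrinkage
        assert t0 <= peak_day <= t1 + 2.0   # within 1/delta_I of the window

    def test_empty_subset_is_baseline_run(self, cd40_patient):
        pt = cd40_patient
        traj = single_mechanism_simulation(pt.params, pt.cytokine, pt.init,
                                           pt.regimen, set(), horizon=30.0)
        assert np.all(traj.column("M_a") == 0.0)

    def test_unknown_mechanism_rejected(self, cd40_patient):
        pt = cd40_patient
        with pytest.raises(ValueError):
            single_mechanism_simulation(pt.params, pt.cytokine, pt.init,
                                        pt.regimen, {"IL1"}, horizon=10.0)


class TestMonotonicity:
    def test_stronger_cd40_does_not_reduce_cd40_share_or_peak(self,
                                                              cd40_patient):
        pt = cd40_patient
        fracs, peaks = [], []
        for scale in (0.5, 1.0, 2.0):
            q = CytokineParams(**{**pt.cytokine.to_dict(),
                                  "beta_C": pt.cytokine.beta_C * scale})
            traj = simulate(pt.params, q, pt.init, pt.regimen, horizon=90.0,
                            track_activation=True)
            dec = decompose_activation(traj)
            fracs.append(dec.fractions["CD40"])
            peaks.append(float(np.max(traj.column("IL6"))))
        assert fracs[0] <= fracs[1] + 1e-6 <= fracs[2] + 2e-6
        assert peaks[0] <= peaks[1] + 1e-6 <= peaks[2] + 2e-6
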