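"""Engine-level behaviour: determinism, conservation, equilibria, and the
hybrid-versus-exact-SSA cross-check on a reduced system."""

import numpy as np
import pytest

import camkii_spine as ck
from camkii_spine import cam, stimulus as stim
from camkii_spine.params import AVOGADRO, ParameterError

FL = 1e-15


def _empty_stimulus(tau=0.005):
    return stim.CaInfluxSchedule(times=np.array([]), n_ions=np.array([], dtype=int),
                                 pulse_tau=tau)


class TestDeterminism:
    def test_hybrid_bit_reproducible(self, params):
        a = ck.run_simulation(params, ck.RunConfig(seed=11, t_end=2.0))
        b = ck.run_simulation(params, ck.RunConfig(seed=11, t_end=2.0))
        assert a.data.equals(b.data)

    def test_exact_ssa_bit_reproducible(self, reduced_params):
        cfg = ck.RunConfig(seed=5, t_end=0.5, engine="exact_ssa", ca_clamp=1e-6)
        a = ck.run_simulation(reduced_params, cfg, stimulus=_empty_stimulus())
        b = ck.run_simulation(reduced_params, cfg, stimulus=_empty_stimulus())
        assert a.data.equals(b.data)

    def test_unknown_engine_rejected(self, params):
        with pytest.raises(ParameterError):
            ck.run_simulation(params, ck.RunConfig(seed=0, t_end=0.1, engine="odes"))


class TestQuiescence:
    def test_no_stimulus_no_phosphorylation(self, params):
        tr = ck.run_simulation(params, ck.RunConfig(seed=2, t_end=5.0),
                               stimulus=_empty_stimulus())
        d = tr.data
        assert d.pT286.max() == 0
        # free Ca2+ hovers near one ion in 0.016 fL at 100 nM
        assert d.ca_free.iloc[-1] == pytest.approx(
            params.ca_baseline * AVOGADRO * params.V_spine, rel=0.05)

    def test_nonnegative_counts_everywhere(self, default_trajectory):
        values = default_trajectory.data.iloc[:, 1:].to_numpy()
        assert np.all(values >= 0)


class TestConservation:
    def test_subunit_and_pp1_books_balance(self, default_trajectory, params):
        d = default_trajectory.data
        # CaM bound to subunits can never exceed the subunit count, and PP1
        # bound can never exceed the pool
        assert d.cam_bound_total.max() <= 720
        assert d.pp1_bound.max() <= params.pp1_count()
        # phosphorylated subunits are a subset of all subunits
        assert d.pT286.max() <= 720
        assert (d.pT286_psd + d.pT286_cyt).equals(d.pT286)

    def test_cam_total_stays_near_bath_level(self, default_trajectory):
        d = default_trajectory.data
        total = d.cam_free_total + d.cam_bound_total
        # exchange with the bath bounds the spine CaM content: it can exceed
        # the initial 289 during the stimulus (influx from the shaft) but
        # stays within a physiological envelope
        assert total.min() > 100
        assert total.max() < 1000

    def test_trapping_off_no_ha_states(self, default_trajectory):
        assert default_trajectory.data.ha_subunits.max() == 0

    def test_competition_code_path_inert_when_scaled_to_zero(self, params):
        """With the block scale at zero the competition branch must leave
        trajectories bit-identical to competition off."""
        base = params.replace(competition=False)
        scaled = params.replace(competition=True, competition_scale=0.0)
        a = ck.run_simulation(base, ck.RunConfig(seed=4, t_end=3.0))
        b = ck.run_simulation(scaled, ck.RunConfig(seed=4, t_end=3.0))
        assert a.data.equals(b.data)


class TestReservoirExchange:
    def test_depleted_spine_recovers_at_k_exchange(self):
        p = ck.load_params(counts={"n_holoenzymes": 0})
        k = p.k_cam_exchange
        tr = ck.run_simulation(p, ck.RunConfig(seed=0, t_end=3.0 / k,
                                               cam_init_zero=True),
                               stimulus=_empty_stimulus())
        d = tr.data
        total = 30e-6 * AVOGADRO * p.V_spine
        i = np.argmin(np.abs(tr.times - 1.0 / k))
        assert d.cam_free_total.iloc[0] < 0.05 * total
        assert d.cam_free_total.iloc[i] == pytest.approx(total * (1 - np.exp(-1)),
                                                         rel=0.05)
        assert d.cam_free_total.iloc[-1] == pytest.approx(total, rel=0.06)

    def test_confined_species_untouched_by_exchange(self, params):
        tr = ck.run_simulation(params, ck.RunConfig(seed=1, t_end=1.0),
                               stimulus=_empty_stimulus())
        assert tr.data.pp1_bound.iloc[-1] == 0
        assert tr.data.pT286.max() == 0


class TestBindingEquilibrium:
    def test_two_state_occupancy_at_kd(self):
        """One CaM among 12 subunits with 12*[CaM] = KD gives 50% occupancy.

        At zero Ca2+ the only species is apo-CaM and no Ca2+ channel can
        fire, so the run is a pure two-state binding/unbinding chain with
        analytic occupancy C/(C + KD)."""
        V = 12.0 / (AVOGADRO * 0.0192075679)  # 12 * c_single = KD_la(CaM0)
        p = ck.load_params(
            counts={"n_holoenzymes": 1},
            volumes={"V_spine_fL": V / FL, "V_psd_fL": 0.1 * V / FL},
            concentrations={"conc_CaM_total_uM": 1.0 / (AVOGADRO * V) * 1e6,
                            "conc_PP1_uM": 0.0},
            exchange={"k_cam_exchange": 0.0},
        )
        t = ck.build_rate_tables(p)
        kd0 = float(t.kd_la[cam.CAM0])
        assert kd0 == pytest.approx(0.0192075679, rel=1e-6)
        tr = ck.run_simulation(p, ck.RunConfig(seed=9, t_end=20.0,
                                               record_dt=0.002, engine="exact_ssa",
                                               ca_clamp=0.0),
                               stimulus=_empty_stimulus())
        occ = tr.data.cam_bound_total.mean()
        # ~2500 independent dwell cycles in 20 s -> s.e. about 1%
        assert occ == pytest.approx(0.5, abs=0.06)


class TestHybridVsExactSSA:
    def test_ensemble_means_agree_on_reduced_system(self, reduced_params):
        """Clamped-Ca drive, 6 holoenzymes / 29 CaM / 2 PP1: the production
        hybrid integrator must agree with the exact Gillespie reference
        within 3 pooled standard errors on mean phosphorylation."""
        p = reduced_params
        n_seeds, t_end = 8, 3.0
        clamp = 2e-6

        def final_pT(engine, seed):
            tr = ck.run_simulation(
                p, ck.RunConfig(seed=seed, t_end=t_end, record_dt=0.05,
                                engine=engine, ca_clamp=clamp),
                stimulus=_empty_stimulus())
            y = tr.data.pT286.to_numpy()
            return y.max(), y[-1]

        hyb = np.array([final_pT("hybrid", s) for s in range(n_seeds)])
        ssa = np.array([final_pT("exact_ssa", 100 + s) for s in range(n_seeds)])
        for col in (0, 1):  # peak and final pT286
            mh, ms = hyb[:, col].mean(), ssa[:, col].mean()
            se = np.sqrt(hyb[:, col].var(ddof=1) / n_seeds
                         + ssa[:, col].var(ddof=1) / n_seeds)
            assert abs(mh - ms) <= 3 * max(se, 0.3)

    def test_ssa_equilibrium_occupancy_matches_analytic_solver(self, params):
        """Long-run species fractions of the discrete chain at clamped Ca2+
        match the null-space solution within 3 s.e. across seeds."""
        p = ck.load_params(
            counts={"n_holoenzymes": 0},
            concentrations={"conc_CaM_total_uM": 29 / (AVOGADRO * 0.016e-15) * 1e6},
            exchange={"k_cam_exchange": 0.0},
        )
        clamp = 1e-6
        expected = ck.equilibrium_cam_distribution(clamp, p)
        seeds = range(4)
        fracs = []
        for s in seeds:
            tr = ck.run_simulation(p, ck.RunConfig(seed=s, t_end=4.0,
                                                   record_dt=0.01,
                                                   engine="exact_ssa",
                                                   ca_clamp=clamp),
                                   stimulus=_empty_stimulus())
            d = tr.data[tr.data.time_s >= 1.0]  # discard burn-in
            tot = d.cam_free_total.mean()
            fracs.append([d[f"cam_free_{n}"].mean() / tot for n in cam.SPECIES_NAMES])
        fracs = np.asarray(fracs)
        mean = fracs.mean(axis=0)
        se = fracs.std(axis=0, ddof=1) / np.sqrt(len(seeds))
        for j in range(9):
            assert abs(mean[j] - expected[j]) <= 3 * max(se[j], 0.01)


class TestLocalization:
    def test_pp1_pools_partition_and_never_mix(self):
        p = ck.load_params(flags={"psd_localization": "camkii_and_pp1",
                                  "trapping": True, "competition": True})
        tr = ck.run_simulation(p, ck.RunConfig(seed=3, t_end=4.0))
        d = tr.data
        # capsule holds half the holoenzymes: psd pT286 stays within its 360
        assert d.pT286_psd.max() <= 360
        assert d.pT286_cyt.max() <= 360
        assert d.pT286_psd.max() > 0

    def test_trajectory_tidy_export(self, default_trajectory):
        tidy = default_trajectory.to_tidy()
        assert set(tidy.columns) == {"time_s", "observable", "count", "compartment"}
        assert (tidy[tidy.observable == "pT286_psd"].compartment == "psd").all()


class TestEnsemble:
    def test_summary_statistics_definitions(self, reduced_params):
        ens = ck.run_ensemble(reduced_params, seeds=range(3), t_end=0.5,
                              record_dt=0.05)
        sd = ens.sd()["pT286"].to_numpy()
        sem = ens.sem()["pT286"].to_numpy()
        np.testing.assert_allclose(sem, sd / np.sqrt(3), rtol=1e-12)
        per_seed = ens.per_seed_observable("pT286")
        np.testing.assert_allclose(per_seed.mean(axis=0),
                                   ens.mean_observable("pT286"), rtol=1e-12)

    def test_single_seed_rejected(self, reduced_params):
        with pytest.raises(ParameterError):
            ck.run_ensemble(reduced_params, seeds=[1], t_end=0.5)

    def test_hdf5_round_trip(self, reduced_params, tmp_path):
        import h5py
        ens = ck.run_ensemble(reduced_params, seeds=range(2), t_end=0.3,
                              record_dt=0.05)
        path = tmp_path / "ens.h5"
        ens.to_hdf5(path)
        with h5py.File(path) as f:
            assert f.attrs["n_seeds"] == 2
            np.testing.assert_allclose(f["mean"][:],
                                       ens.mean().iloc[:, 1:].to_numpy())
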