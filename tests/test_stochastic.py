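"""Stochastic layers: truncated-Gaussian rates, sine-Wiener bounded noise,
Poisson jumps, the Euler-Maruyama engine and seeded ensembles."""

import math

import numpy as np
import pytest

from gliomanet.dynamics import integrate_deterministic, assemble_rhs
from gliomanet.stochastic import (JumpProcess, NoiseSpec, bounded_noise_step,
                                  integrate_stochastic,
                                  perturb_rate_truncated_gaussian,
                                  poisson_event_count, run_ensemble,
                                  run_seed_for, simulate)
from .conftest import make_toy_spec


class TestTruncatedGaussianRate:
    def test_noise_free_limit(self):
        assert perturb_rate_truncated_gaussian(3.0, 0.0) == 3.0

    def test_moments_and_truncation(self):
        rng = np.random.default_rng(11)
        draws = perturb_rate_truncated_gaussian(2.0, 0.1, rng=rng,
                                                size=100_000)
        assert abs(draws.mean() - 2.0) / 2.0 < 0.01
        assert draws.min() >= 0.0 and draws.max() <= 4.0

    def test_tight_bounds_are_respected(self):
        rng = np.random.default_rng(5)
        draws = perturb_rate_truncated_gaussian(2.0, 0.5, bounds=(0.0, 2.0),
                                                rng=rng, size=10_000)
        assert draws.max() <= 2.0


class TestBoundedNoise:
    def test_frozen_limit_at_infinite_correlation_time(self):
        rng = np.random.default_rng(0)
        z = 0.37
        for _ in range(50):
            z2 = bounded_noise_step(z, dt=0.01, tau_n=1e12, rng=rng)
            assert z2 == pytest.approx(z, abs=1e-4)
            z = z2

    def test_confinement_and_stationary_moments(self):
        rng = np.random.default_rng(42)
        n = 300_000
        z = 0.0
        zs = np.empty(n)
        for i in range(n):
            z = bounded_noise_step(z, dt=0.05, tau_n=0.5, rng=rng)
            zs[i] = z
        assert zs.min() >= -1.0 and zs.max() <= 1.0
        # sine of a diffusing phase: arcsine-shaped stationary law with
        # mean 0 and second moment 1/2
        assert abs(zs.mean()) < 0.01
        assert abs((zs ** 2).mean() - 0.5) < 0.01

    def test_input_domain(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            bounded_noise_step(1.5, 0.01, 1.0, rng)
        with pytest.raises(ValueError):
            bounded_noise_step(0.0, -0.01, 1.0, rng)


class TestPoissonEventCount:
    def test_null_process(self):
        rng = np.random.default_rng(1)
        count, times = poisson_event_count(lambda s, t: 0.0, 0.0, 10.0,
                                           rng=rng)
        assert count == 0 and times == []

    def test_homogeneous_moments(self):
        rng = np.random.default_rng(7)
        counts = np.array([
            poisson_event_count(lambda s, t: 5.0, 0.0, 10.0, rng=rng,
                                lam_max=5.0)[0]
            for _ in range(10_000)])
        assert abs(counts.mean() - 50.0) / 50.0 < 0.02
        assert abs(counts.var() - 50.0) / 50.0 < 0.05

    def test_linear_rate_mean(self):
        # integral of lambda(t) = t over [0, 2] is 2
        rng = np.random.default_rng(3)
        counts = np.array([
            poisson_event_count(lambda s, t: t, 0.0, 2.0, rng=rng,
                                lam_max=2.0)[0]
            for _ in range(10_000)])
        assert abs(counts.mean() - 2.0) / 2.0 < 0.03

    def test_infinite_rate_is_refused(self):
        with pytest.raises(ValueError):
            poisson_event_count(lambda s, t: math.inf, 0.0, 1.0,
                                rng=np.random.default_rng(0),
                                lam_max=math.inf)


class TestEngineContracts:
    def test_deterministic_limit_matches_euler_ode(self, spec, model):
        tr_sde = integrate_stochastic(model, noise=NoiseSpec.quiet(),
                                      jumps=[], t_span=60.0, dt=0.01, seed=3)
        rhs = assemble_rhs(spec)
        tr_ode = integrate_deterministic(rhs, model.initial_state(), 60.0,
                                         method="euler", step=0.01)
        scale = np.maximum(np.abs(tr_ode.values), 1.0)
        assert np.max(np.abs(tr_sde.values - tr_ode.values) / scale) < 1e-9

    def test_seed_reproducibility_bitwise(self, model, noise, jumps,
                                          tmp_path):
        a = integrate_stochastic(model, noise=noise, jumps=jumps,
                                 t_span=30.0, dt=0.01, seed=12)
        b = integrate_stochastic(model, noise=noise, jumps=jumps,
                                 t_span=30.0, dt=0.01, seed=12)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, sidecar=False)
        b.to_csv(pb, sidecar=False)
        assert pa.read_bytes() == pb.read_bytes()
        c = integrate_stochastic(model, noise=noise, jumps=jumps,
                                 t_span=30.0, dt=0.01, seed=13)
        assert not np.array_equal(a.values, c.values)

    def test_jump_bookkeeping_conservation(self):
        # pure immigration into an otherwise inert cell: the cells added
        # must equal the independently replayed sum of event magnitudes
        toy = make_toy_spec(prolif=0.0, decay=0.0, secretion=0.0,
                            cell_init=0.0)
        jp = JumpProcess("C", kind="recruitment", rate0=4.0,
                         magnitude_mean=3.0)
        t_span, dt, seed = 20.0, 0.01, 21
        tr = integrate_stochastic(toy, noise=None, jumps=[jp],
                                  t_span=t_span, dt=dt, seed=seed)
        # replay the identical pregenerated stream
        from gliomanet.dynamics import compile_model
        from gliomanet.stochastic import PROD_NOISE_REFRESH_DAYS, _pregenerate
        m = compile_model(toy)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n_steps = int(round(t_span / dt))
        xi_stride = max(1, int(round(PROD_NOISE_REFRESH_DAYS / dt)))
        _, _, _, u, mag, _ = _pregenerate(rng, n_steps, m, [jp], xi_stride)
        total = 0.0
        p = jp.rate0 * dt
        for step in range(n_steps):
            acc = math.exp(-p)
            cdf = acc
            k = 0
            while u[step, 0] > cdf and k < 50:
                k += 1
                acc *= p / k
                cdf += acc
            total += k * mag[step, 0]
        assert tr.species("C")[-1] == pytest.approx(total, rel=1e-12)

    def test_nonnegativity_under_noise(self, model, noise, jumps):
        tr = integrate_stochastic(model, noise=noise, jumps=jumps,
                                  t_span=40.0, dt=0.01, seed=2)
        assert np.all(tr.values >= 0.0)


class TestEnsembles:
    def test_single_rep_summary_equals_trajectory(self, model, noise, jumps):
        ens = run_ensemble(model, noise=noise, jumps=jumps, t_span=20.0,
                           dt=0.02, n_reps=1, master_seed=4)
        tr = ens.trajectories[0]
        for k, sid in enumerate(ens.species_ids):
            np.testing.assert_array_equal(ens.summary[sid]["mean"],
                                          tr.values[:, k])
            np.testing.assert_array_equal(ens.summary[sid]["q50"],
                                          tr.values[:, k])

    def test_ensemble_reproducible_and_seeds_derived(self, model, noise,
                                                     jumps):
        e1 = run_ensemble(model, noise=noise, jumps=jumps, t_span=15.0,
                          dt=0.02, n_reps=3, master_seed=9)
        e2 = run_ensemble(model, noise=noise, jumps=jumps, t_span=15.0,
                          dt=0.02, n_reps=3, master_seed=9)
        assert e1.run_seeds == e2.run_seeds
        np.testing.assert_array_equal(e1.trajectories[2].values,
                                      e2.trajectories[2].values)
        expected = [int(run_seed_for(9, i).generate_state(1)[0])
                    for i in range(3)]
        assert e1.run_seeds == expected

    def test_requires_at_least_one_rep(self, model):
        with pytest.raises(ValueError):
            run_ensemble(model, n_reps=0)

    def test_step_halving_stability_of_ensemble_mean(self, model, noise,
                                                     jumps):
        means = {}
        for dt in (0.02, 0.01):
            ens = run_ensemble(model, noise=noise, jumps=jumps, t_span=365.0,
                               dt=dt, n_reps=8, master_seed=17,
                               keep_trajectories=False)
            means[dt] = ens.summary["GC"]["mean"][-1]
        assert abs(means[0.01] - means[0.02]) / means[0.01] < 0.02
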