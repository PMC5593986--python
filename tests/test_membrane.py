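"""Brownian dynamics engine: geometry building, stepping rules, MSD."""

import numpy as np
import pytest

from spotvar import (
    Meshwork,
    MembraneModel,
    NanoDomain,
    PackingError,
    SimConfig,
    TimestepError,
    build_membrane,
    msd,
    simulate,
)


class TestBuildMembrane:
    def test_zero_domains_gives_free_model(self):
        m = build_membrane(n_domains=0)
        assert m.domains == ()
        assert m.scenario_tag == "free"

    def test_seeded_layout_is_reproducible(self):
        a = build_membrane(n_domains=20, domain_radius=0.05, box_edge=2.0, seed=7)
        b = build_membrane(n_domains=20, domain_radius=0.05, box_edge=2.0, seed=7)
        assert [d.center for d in a.domains] == [d.center for d in b.domains]

    def test_excessive_area_fraction_raises(self):
        # 0.6 of the box covered by domains is not packable
        with pytest.raises(PackingError):
            build_membrane(n_domains=306, domain_radius=0.05, box_edge=2.0)

    def test_domains_do_not_overlap(self):
        m = build_membrane(n_domains=30, domain_radius=0.06, seed=1)
        c = np.array([d.center for d in m.domains])
        for i in range(len(c)):
            d = np.hypot(*(c[i] - c[i + 1:]).T)
            assert np.all(d >= 2 * 0.06 - 1e-12)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            MembraneModel(box_edge=-1.0, D_out=1.0)
        with pytest.raises(ValueError):
            NanoDomain(center=(0.5, 0.5), radius=0.1, D_in=1.0, p_enter=1.5)
        with pytest.raises(ValueError):
            Meshwork(mesh_size=0.1, p_hop=-0.2)
        with pytest.raises(ValueError):
            # overlapping domains rejected by the model itself
            MembraneModel(
                box_edge=2.0, D_out=1.0,
                domains=[
                    NanoDomain((1.0, 1.0), 0.1, 1.0),
                    NanoDomain((1.05, 1.0), 0.1, 1.0),
                ],
            )


class TestSimulate:
    def test_zero_diffusivity_is_stationary(self):
        m = build_membrane(D_out=0.0)
        traj = simulate(m, SimConfig(n_particles=5, n_steps=100, seed=0))
        assert np.all(traj.positions == traj.positions[0])

    def test_seed_determinism(self, free_model):
        cfg = SimConfig(n_particles=10, n_steps=500, seed=11)
        a = simulate(free_model, cfg)
        b = simulate(free_model, cfg)
        assert np.array_equal(a.positions, b.positions)

    def test_particle_count_conserved_and_in_box(self, free_traj):
        assert free_traj.positions.shape[1] == 50
        assert np.all(free_traj.positions >= 0)
        assert np.all(free_traj.positions < free_traj.box_edge)

    def test_timestep_precondition(self):
        m = build_membrane(n_domains=5, domain_radius=0.02, D_out=5.0, seed=0)
        with pytest.raises(TimestepError, match="domain radius"):
            simulate(m, SimConfig(n_particles=2, dt=1e-4, n_steps=10, seed=0))

    def test_absorbing_trap_limit(self):
        # p_exit = 0 with particles started inside a domain: never leave
        dom = NanoDomain(center=(1.0, 1.0), radius=0.2, D_in=1.0,
                         p_enter=1.0, p_exit=0.0)
        m = MembraneModel(box_edge=2.0, D_out=1.0, domains=[dom],
                          scenario_tag="trapped")
        cfg = SimConfig(n_particles=20, dt=1e-5, n_steps=2000, seed=5)
        init = np.full((20, 2), 1.0)
        traj = simulate(m, cfg, init_positions=init)
        r = np.hypot(traj.positions[..., 0] - 1.0, traj.positions[..., 1] - 1.0)
        assert np.all(r <= 0.2 + 1e-12)

    def test_trap_occupancy_enrichment(self):
        # p_enter=1, p_exit<1: steady-state density inside exceeds outside
        m = build_membrane(n_domains=12, domain_radius=0.15, box_edge=2.0,
                           D_out=1.0, D_in=1.0, p_enter=1.0, p_exit=0.2,
                           seed=3)
        traj = simulate(m, SimConfig(n_particles=100, n_steps=20000, seed=9))
        tail = traj.positions[10000:]
        c = np.array([d.center for d in m.domains])
        inside = np.zeros(tail.shape[:2], dtype=bool)
        for (cx, cy) in c:
            inside |= np.hypot(tail[..., 0] - cx, tail[..., 1] - cy) <= 0.15
        area_in = 12 * np.pi * 0.15 ** 2
        frac_area = area_in / 4.0
        frac_occ = inside.mean()
        # density ratio = occupancy odds over area odds
        assert frac_occ / frac_area > 1.5

    def test_meshwork_slows_long_time_diffusion(self):
        m = MembraneModel(box_edge=2.0, D_out=2.0,
                          mesh=Meshwork(0.15, 0.05), scenario_tag="meshwork")
        traj = simulate(m, SimConfig(n_particles=100, n_steps=2 ** 14, seed=2))
        tab = msd(traj, [256, 512, 1024, 2048, 4096])
        slope = np.polyfit(tab.lag_time, tab.msd, 1)[0]
        assert slope / 4 < 0.75 * 2.0  # clearly below the free diffusivity


class TestMsd:
    def test_stationary_msd_is_zero(self):
        m = build_membrane(D_out=0.0)
        traj = simulate(m, SimConfig(n_particles=3, n_steps=50, seed=0))
        tab = msd(traj, [1, 5, 10])
        assert np.allclose(tab["msd"], 0.0)

    def test_free_diffusion_recovers_D(self, free_traj):
        # MSD = 4 D t oracle at lags <= 10% of the trajectory
        lags = [1, 2, 4, 8, 16, 32, 64, 128]
        tab = msd(free_traj, lags)
        slope = np.polyfit(tab.lag_time, tab.msd, 1)[0]
        assert slope / 4 == pytest.approx(2.0, rel=0.10)

    def test_free_diffusion_within_three_se(self, free_model):
        # per-lag check against 4*D*t using scatter across particles
        traj = simulate(free_model, SimConfig(n_particles=80, n_steps=4096, seed=12))
        un = traj.unwrapped()
        for k in (8, 64, 256):
            d = un[k:] - un[:-k]
            sq = np.sum(d * d, axis=-1)
            per_particle = sq.mean(axis=0)
            se = per_particle.std(ddof=1) / np.sqrt(per_particle.size)
            expect = 4 * 2.0 * k * traj.dt
            assert abs(per_particle.mean() - expect) < 3 * se

    def test_two_point_base_case(self):
        m = build_membrane(D_out=1.0)
        traj = simulate(m, SimConfig(n_particles=4, n_steps=2, seed=1))
        tab = msd(traj, [1])
        un = traj.unwrapped()
        step = un[1] - un[0]
        assert tab["msd"][0] == pytest.approx(np.mean(np.sum(step ** 2, -1)))

    def test_lag_bounds_rejected(self, free_traj):
        with pytest.raises(ValueError):
            msd(free_traj, [free_traj.n_steps])
        with pytest.raises(ValueError):
            msd(free_traj, [0])
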