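"""Monte Carlo engine: decays, emission, transport, crystal detection."""

import math

import numpy as np
import pytest
from scipy import integrate

from monopet.constants import WATER, FWHM_TO_SIGMA
from monopet.mc import (
    PhotonBatch,
    PhysicsModel,
    Scenario,
    SinglesList,
    compton_energy,
    detect_in_crystal,
    emit_pair,
    isotropic_directions,
    run_simulation,
    sample_decays,
    sample_klein_nishina,
    survival_filter,
    transport_photons,
    transport_fast,
)
from monopet.phantoms import (
    CylinderZ,
    EMPTY_PHANTOM,
    PhantomModel,
    make_sensitivity_source,
)


class TestDecaySampling:
    def test_poisson_count_and_uniform_times(self, rng):
        src = make_sensitivity_source(activity=1e6)
        times, pos = sample_decays(src, 0.1, rng)
        mean = 1e5
        assert abs(len(times) - mean) < 5 * math.sqrt(mean)
        assert np.all(np.diff(times) >= 0)
        assert times.max() <= 0.1e9
        assert abs(times.mean() - 0.05e9) < 5 * 0.1e9 / math.sqrt(12 * mean)

    def test_zero_activity_empty_stream(self, rng):
        src = make_sensitivity_source(activity=0.0)
        times, pos = sample_decays(src, 1.0, rng)
        assert len(times) == 0

    def test_invalid_duration(self, rng):
        with pytest.raises(ValueError):
            sample_decays(make_sensitivity_source(), 0.0, rng)


class TestEmission:
    def test_back_to_back_exact_antipode(self, rng):
        pos = np.zeros((1000, 3))
        _, d1, d2 = emit_pair(pos, "back_to_back", PhysicsModel(), rng)
        assert np.allclose(np.einsum("ij,ij->i", d1, d2), -1.0)

    def test_directions_isotropic(self, rng):
        n = 100_000
        d = isotropic_directions(n, rng)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert np.all(np.abs(d.mean(axis=0)) < 3.0 / math.sqrt(n))

    def test_acolinearity_per_axis_fwhm(self, rng):
        physics = PhysicsModel(positron_range=False)
        pos = np.zeros((200_000, 3))
        _, d1, d2 = emit_pair(pos, "f18", physics, rng)
        # angle between d2 and the exact antipode, projected on one axis
        anti = -d1
        cross = np.linalg.norm(np.cross(anti, d2), axis=1)
        dev = np.arcsin(np.clip(cross, -1, 1))  # total deviation angle
        # two Gaussian components of FWHM 0.5 deg -> Rayleigh total;
        # check the per-axis sigma through the Rayleigh mean
        sigma = math.radians(0.5) * FWHM_TO_SIGMA
        expected_mean = sigma * math.sqrt(math.pi / 2.0)
        assert dev.mean() == pytest.approx(expected_mean, rel=0.02)

    def test_positron_range_mean_displacement(self, rng):
        physics = PhysicsModel()
        pos = np.zeros((200_000, 3))
        annih, _, _ = emit_pair(pos, "f18", physics, rng)
        r = np.linalg.norm(annih, axis=1)
        assert r.mean() == pytest.approx(0.6, rel=0.02)  # mm


class TestComptonKinematics:
    @pytest.mark.parametrize(
        "cos_theta,expected",
        [(-1.0, 511.0 / 3.0), (0.0, 255.5), (1.0, 511.0)],
    )
    def test_closed_cases(self, cos_theta, expected):
        assert compton_energy(np.array([511.0]), np.array([cos_theta]))[0] == (
            pytest.approx(expected)
        )

    def test_klein_nishina_mean_matches_quadrature(self, rng):
        def kn(cos_t, alpha=1.0):
            ratio = 1.0 / (1.0 + alpha * (1.0 - cos_t))
            return ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_t**2))

        norm, _ = integrate.quad(kn, -1, 1)
        mean_ref, _ = integrate.quad(lambda c: c * kn(c) / norm, -1, 1)
        sample = sample_klein_nishina(np.full(200_000, 511.0), rng)
        assert sample.mean() == pytest.approx(mean_ref, abs=4 * sample.std() / math.sqrt(len(sample)))


def _slab_phantom(thickness_mm: float) -> PhantomModel:
    cyl = CylinderZ(WATER, 0.0, np.zeros(3), thickness_mm / 2.0, 500.0)
    return PhantomModel([cyl], [-1])


def _beam(n: int) -> PhotonBatch:
    pos = np.tile([-300.0, 0.0, 0.0], (n, 1))
    dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
    return PhotonBatch(
        pos,
        dirs,
        np.full(n, 511.0),
        np.zeros(n, dtype=np.int16),
        np.zeros(n),
        np.ones(n, dtype=bool),
    )


class TestTransport:
    def test_vacuum_phantom_unchanged(self, rng):
        batch = _beam(100)
        out = transport_photons(batch, EMPTY_PHANTOM, rng)
        assert np.all(out.alive)
        assert np.all(out.n_scatters == 0)
        assert np.all(out.energy == 511.0)

    @pytest.mark.parametrize("engine", ["numpy", "numba"])
    def test_unscattered_survival_matches_beer_lambert(self, engine, rng):
        n = 60_000
        phantom = _slab_phantom(100.0)
        batch = _beam(n)
        if engine == "numpy":
            out = transport_photons(batch, phantom, rng)
        else:
            out = transport_fast(batch, phantom, rng)
        unscattered = out.alive & (out.n_scatters == 0)
        expected = math.exp(-WATER.mu_511 * 100.0)
        err = 3 * math.sqrt(expected * (1 - expected) / n)
        assert abs(unscattered.mean() - expected) < err

    def test_energy_conserved_and_degraded(self, rng):
        phantom = _slab_phantom(200.0)
        out = transport_fast(_beam(20_000), phantom, rng)
        scattered = out.n_scatters > 0
        assert np.all(out.energy[scattered] < 511.0)
        assert np.all(out.energy[out.alive] >= 50.0)

    def test_survival_filter_matches_analytic(self, rng):
        n = 100_000
        phantom = _slab_phantom(100.0)
        pos = np.tile([-300.0, 0.0, 0.0], (n, 1))
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        keep = survival_filter(pos, dirs, phantom, rng)
        expected = math.exp(-WATER.mu_511 * 100.0)
        assert keep.mean() == pytest.approx(expected, abs=3 * math.sqrt(expected / n))


class TestCrystalDetection:
    def _detect(self, geom, n, rng, physics=None):
        physics = physics or PhysicsModel()
        batch = _beam(n)
        ids = np.arange(n, dtype=np.int64)
        t0 = np.zeros(n)
        return detect_in_crystal(geom, ids, t0, batch, physics, rng)

    def test_normal_incidence_interaction_probability(self, geom_a, rng):
        n = 50_000
        singles = self._detect(geom_a, n, rng)
        expected = 1.0 - math.exp(-0.087 * 16.0)  # 0.752
        assert len(singles) / n == pytest.approx(expected, abs=0.01)

    def test_energy_blur_fwhm_at_511(self, geom_a, rng):
        physics = PhysicsModel(p_full=1.0)  # full deposits only
        singles = self._detect(geom_a, 50_000, rng, physics)
        fwhm = np.std(singles.energy) / FWHM_TO_SIGMA
        assert fwhm == pytest.approx(0.115 * 511.0, rel=0.03)

    def test_interaction_points_inside_slab(self, geom_a, rng):
        singles = self._detect(geom_a, 20_000, rng)
        r = np.hypot(singles.position[:, 0], singles.position[:, 1])
        assert np.all(r >= 350.0 - 1e-6)
        assert np.all(r <= 366.0 + 25.0)  # depth along the ray, flat slab

    def test_pair_time_difference_fwhm_is_ctr(self, geom_a, rng):
        """A centred vacuum point source: dt distribution has 200 ps FWHM."""
        src_pos = np.zeros((40_000, 3))
        _, d1, d2 = emit_pair(src_pos, "back_to_back", PhysicsModel(), rng)
        n = len(src_pos)
        batch = PhotonBatch(
            np.concatenate([src_pos, src_pos]),
            np.concatenate([d1, d2]),
            np.full(2 * n, 511.0),
            np.zeros(2 * n, dtype=np.int16),
            np.zeros(2 * n),
            np.ones(2 * n, dtype=bool),
        )
        ids = np.concatenate([np.arange(n), np.arange(n)]).astype(np.int64)
        singles = detect_in_crystal(
            geom_a, ids, np.zeros(2 * n), batch, PhysicsModel(), rng
        )
        order = np.argsort(singles.decay_id, kind="stable")
        s = singles.select(order)
        ids_, counts = np.unique(s.decay_id, return_counts=True)
        firsts = np.searchsorted(s.decay_id, ids_[counts == 2])
        dt = s.time[firsts] - s.time[firsts + 1]
        # equal path lengths: jitter-free dt is 0, so the spread is pure CTR
        fwhm_ps = np.std(dt) / FWHM_TO_SIGMA * 1e3
        assert fwhm_ps == pytest.approx(200.0, rel=0.05)
        assert abs(np.mean(dt)) < 5 * np.std(dt) / math.sqrt(len(dt))


class TestRunSimulation:
    def test_photon_bookkeeping_partition(self, geom_a):
        from monopet.phantoms import make_scatter_phantom

        phantom, source = make_scatter_phantom(0.5)
        counters = {}
        run_simulation(
            Scenario(geom_a, source, phantom),
            2e5 / source.total_activity,
            rng=5,
            counters=counters,
        )
        assert counters["photons"] == 2 * counters["decays"]
        assert (
            counters["absorbed_phantom"] + counters["escaped"]
            == counters["photons"]
        )
        assert counters["detected"] + counters["missed"] == counters["escaped"]

    def test_empty_source_empty_stream(self, geom_a):
        source = make_sensitivity_source(activity=0.0)
        singles = run_simulation(Scenario(geom_a, source), 1.0, rng=0)
        assert len(singles) == 0

    def test_event_budget_guard(self, geom_a):
        source = make_sensitivity_source()  # 5 MBq
        with pytest.raises(ValueError):
            run_simulation(Scenario(geom_a, source), 1e5, rng=0, max_decays=1e6)

    def test_bitwise_reproducibility(self, geom_a):
        source = make_sensitivity_source()
        a = run_simulation(Scenario(geom_a, source), 0.02, rng=42)
        b = run_simulation(Scenario(geom_a, source), 0.02, rng=42)
        for field in ("decay_id", "module", "position", "energy", "time"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_stream_is_time_ordered(self, geom_a):
        source = make_sensitivity_source()
        singles = run_simulation(Scenario(geom_a, source), 0.02, rng=3)
        assert np.all(np.diff(singles.time) >= 0)

    def test_design_b_doubles_line_source_singles(self, geom_a, geom_b):
        source = make_sensitivity_source()
        a = run_simulation(Scenario(geom_a, source), 0.04, rng=9)
        b = run_simulation(Scenario(geom_b, source), 0.04, rng=9)
        ratio = len(b) / len(a)
        assert 1.75 < ratio < 2.15  # doubled axial coverage
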