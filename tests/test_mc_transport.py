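"""Photon transport physics: conservation, phase function, timing, gating,
overlap correction, B-scan assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import miroct as m
from miroct.mc_transport import hg_sample


def _ledger_total(ledger):
    return (ledger["absorbed"] + ledger["exited_top"]
            + ledger["exited_other"] + ledger["time_expired"]
            + ledger["roulette_net"])


class TestTimeGrid:
    def test_depth_sampling(self):
        tg = m.TimeGrid()
        assert tg.n_gates == 600
        assert tg.dz_um == pytest.approx(3.5975, abs=0.0005)

    def test_non_integral_grid_rejected(self):
        with pytest.raises(ValueError):
            m.TimeGrid(t_total_ps=1.0, dt_fs=37.0)


class TestSimulate:
    def test_ballistic_conservation(self, time_grid):
        """No scattering, no absorption: Fresnel-split weight is fully
        accounted for."""
        dom = m.VoxelDomain.uniform((20, 20, 60), n=1.0)
        dom.n[:, :, 30:] = 1.5
        src = m.McSource(x_um=50.0, y_um=50.0, width_um=5.0,
                         photon_count=5000, seed=1)
        records, absorbed = m.simulate(dom, src, time_grid, na=0.1)
        assert absorbed.sum() == 0.0
        total = _ledger_total(records.ledger)
        assert total == pytest.approx(records.ledger["launched"], rel=1e-9)

    def test_scattering_conservation(self, time_grid):
        dom = m.VoxelDomain.uniform((20, 20, 40), mua=0.5, mus=10.0, g=0.8,
                                    n=1.4)
        src = m.McSource(x_um=50.0, y_um=50.0, width_um=5.0,
                         photon_count=5000, seed=2)
        records, absorbed = m.simulate(dom, src, time_grid, na=0.1)
        total = _ledger_total(records.ledger)
        assert total == pytest.approx(records.ledger["launched"], rel=1e-6)
        assert absorbed.sum() == pytest.approx(records.ledger["absorbed"],
                                               rel=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_conservation_property_random_domains(self, seed):
        """Weight is conserved for arbitrary random voxel domains."""
        rng = np.random.default_rng(seed)
        dims = (8, 8, 12)
        dom = m.VoxelDomain(
            mua=rng.uniform(0.0, 2.0, dims),
            mus=rng.uniform(0.0, 30.0, dims),
            g=rng.uniform(-0.5, 0.95, dims),
            n=rng.uniform(1.0, 2.2, dims),
            voxel_size_um=5.0)
        src = m.McSource(x_um=20.0, y_um=20.0, width_um=4.0,
                         photon_count=500, seed=seed)
        records, _ = m.simulate(dom, src, m.TimeGrid(), na=0.1)
        total = _ledger_total(records.ledger)
        assert total == pytest.approx(records.ledger["launched"], rel=1e-6)

    def test_determinism_bit_identical(self, time_grid):
        dom = m.VoxelDomain.uniform((10, 10, 20), mus=5.0, g=0.5, n=1.3)
        src = m.McSource(x_um=25.0, y_um=25.0, width_um=5.0,
                         photon_count=2000, seed=77)
        r1, a1 = m.simulate(dom, src, time_grid, na=0.1)
        r2, a2 = m.simulate(dom, src, time_grid, na=0.1)
        assert np.array_equal(r1.t_ps, r2.t_ps)
        assert np.array_equal(r1.weight, r2.weight)
        assert np.array_equal(a1, a2)

    def test_source_outside_domain_rejected(self, time_grid):
        dom = m.VoxelDomain.uniform((10, 10, 10))
        src = m.McSource(x_um=500.0, y_um=25.0, photon_count=10)
        with pytest.raises(ValueError):
            m.simulate(dom, src, time_grid, na=0.1)

    def test_henyey_greenstein_mean_cosine(self):
        """The empirical mean deflection cosine recovers g within 3 sigma."""
        g = 0.9
        n = 200_000
        cosines = hg_sample(g, n, seed=5)
        # var of HG cosine: <cos^2> - g^2 with <cos^2> = 1 - 2(1-g^2)*I
        se = cosines.std(ddof=1) / np.sqrt(n)
        assert abs(cosines.mean() - g) < 3.0 * se

    def test_isotropic_limit(self):
        cosines = hg_sample(0.0, 100_000, seed=6)
        se = cosines.std(ddof=1) / np.sqrt(cosines.size)
        assert abs(cosines.mean()) < 3.0 * se


class TestExtractAscan:
    def test_ballistic_timing_gate(self, time_grid):
        """A specular interface 500 µm deep in an index-matched medium
        echoes into the gate holding t = 2*500 µm/c = 3.336 ps (gate 139,
        counting from 1)."""
        dom = m.VoxelDomain.uniform((40, 40, 200), n=1.0)
        dom.n[:, :, 100:] = 1.5
        src = m.McSource(x_um=100.0, y_um=100.0, width_um=5.0,
                         photon_count=5000, seed=7)
        records, _ = m.simulate(dom, src, time_grid, na=0.1)
        ascan = m.extract_mc_ascan(records, time_grid, na=0.1)
        peak_gate = int(np.argmax(ascan.flux))
        assert peak_gate == 138  # zero-based index of the 139th gate
        assert abs(ascan.depth_um[peak_gate] - 500.0) <= time_grid.dz_um
        # Fresnel normal-incidence reflectance of n=1 -> 1.5
        assert ascan.flux[peak_gate] == pytest.approx((0.5 / 2.5) ** 2,
                                                      rel=1e-6)

    def test_na_acceptance_monotone(self, time_grid):
        dom = m.VoxelDomain.uniform((20, 20, 30), mus=20.0, g=0.3, n=1.4)
        src = m.McSource(x_um=50.0, y_um=50.0, width_um=5.0,
                         photon_count=5000, seed=8)
        records, _ = m.simulate(dom, src, time_grid, na=0.1)
        w_small = m.extract_mc_ascan(records, time_grid, na=0.1).flux.sum()
        w_full = m.extract_mc_ascan(records, time_grid, na=1.0).flux.sum()
        assert w_full >= w_small > 0.0

    def test_index_matched_nonscattering_is_dark(self, time_grid):
        dom = m.VoxelDomain.uniform((10, 10, 20), n=1.0)
        src = m.McSource(x_um=25.0, y_um=25.0, width_um=5.0,
                         photon_count=1000, seed=9)
        records, _ = m.simulate(dom, src, time_grid, na=0.1)
        ascan = m.extract_mc_ascan(records, time_grid, na=0.1)
        assert np.all(ascan.flux == 0.0)


class TestOverlapCorrection:
    def test_in_focus_identity(self):
        cfg = m.OverlapCorrection(w0_um=10.0, lambda_um=4.0, z_focus_um=50.0)
        assert m.overlap_correction(50.0, cfg) == pytest.approx(1.0,
                                                                rel=1e-12)

    def test_matches_quadrature_of_defining_integral(self):
        """Closed form against radial quadrature of the two-Gaussian overlap:
        the reflected beam at depth z looks like the free beam at distance
        2(z - zF) from focus."""
        w0, lam, dz = 10.0, 4.0, 100.0
        cfg = m.OverlapCorrection(w0_um=w0, lambda_um=lam, z_focus_um=0.0)
        got = m.overlap_correction(dz, cfg)
        w2 = w0 * np.sqrt(1.0 + (2.0 * dz * lam / (np.pi * w0**2)) ** 2)
        r = np.linspace(0.0, 30.0 * max(w0, w2), 400_001)
        u1 = np.exp(-(r**2) / w0**2)
        u2 = np.exp(-(r**2) / w2**2)
        cross = np.trapezoid(u1 * u2 * r, r)
        n1 = np.trapezoid(u1**2 * r, r)
        n2 = np.trapezoid(u2**2 * r, r)
        oracle = cross**2 / (n1 * n2)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_far_field_asymptote(self):
        """C*(z - zF)^2 converges to pi^2 w0^4 / lambda^2 far from focus."""
        cfg = m.OverlapCorrection(w0_um=10.0, lambda_um=4.0, z_focus_um=0.0)
        dz = 1e7
        limit = np.pi**2 * 10.0**4 / 4.0**2
        assert m.overlap_correction(dz, cfg) * dz**2 == pytest.approx(
            limit, rel=1e-3)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            m.OverlapCorrection(w0_um=0.0, lambda_um=4.0)


class TestApplyCorrections:
    def _ascan(self, time_grid):
        flux = np.linspace(1.0, 2.0, time_grid.n_gates)
        return m.McAScan(flux=flux, depth_um=time_grid.depth_axis_um())

    def test_identity_when_unit_corrections(self, time_grid):
        a = self._ascan(time_grid)
        out = m.apply_corrections(a, rolloff=np.ones(time_grid.n_gates))
        assert np.array_equal(out.flux, a.flux)

    def test_constant_flux_peaks_at_focus(self, time_grid):
        flux = np.ones(time_grid.n_gates)
        a = m.McAScan(flux=flux, depth_um=time_grid.depth_axis_um())
        cfg = m.OverlapCorrection(w0_um=15.0, lambda_um=4.0, z_focus_um=425.0)
        out = m.apply_corrections(a, overlap=cfg)
        z_max = out.depth_um[np.argmax(out.flux)]
        assert abs(z_max - 425.0) <= time_grid.dz_um

    def test_elementwise_product_oracle(self, time_grid):
        a = self._ascan(time_grid)
        roll = m.rolloff_attenuation(a.depth_um, 2.7,
                                     np.sqrt(3576.0 * 4625.0)) ** 2
        cfg = m.OverlapCorrection(w0_um=15.0, lambda_um=4.0, z_focus_um=50.0)
        out = m.apply_corrections(a, rolloff=roll, overlap=cfg)
        oracle = a.flux * roll * m.overlap_correction(a.depth_um, cfg)
        assert np.allclose(out.flux, oracle, rtol=1e-12)

    def test_depth_mismatch_rejected(self, time_grid):
        a = self._ascan(time_grid)
        with pytest.raises(ValueError):
            m.apply_corrections(a, rolloff=np.ones(10))


class TestBScan:
    def test_line_count_bookkeeping(self):
        assert len(m.bscan_line_positions(7000.0, 10.0)) == 700

    def test_step_larger_than_domain_rejected(self):
        with pytest.raises(ValueError):
            m.bscan_line_positions(100.0, 200.0)

    def test_fixed_seed_uniform_domain_identical_lines(self):
        # wide domain + short time cap: no photon feels the side walls, so
        # equal seeds must give bit-identical lines at every position
        dom = m.VoxelDomain.uniform((400, 10, 20), mua=5.0, mus=100.0,
                                    g=0.0, n=1.4)
        tg = m.TimeGrid(t_total_ps=2.4, dt_fs=24.0)
        b = m.run_mc_bscan(dom, tg, na=0.5, lateral_step_um=1000.0,
                           beam_width_um=5.0, photons_per_line=500,
                           seed=4, seed_policy="fixed")
        assert b.image.shape[1] == 2
        assert np.array_equal(b.image[:, 0], b.image[:, 1])

    def test_per_line_seeds_differ(self):
        dom = m.VoxelDomain.uniform((20, 10, 20), mus=10.0, g=0.5, n=1.4)
        tg = m.TimeGrid(t_total_ps=2.4, dt_fs=24.0)
        b = m.run_mc_bscan(dom, tg, na=0.5, lateral_step_um=50.0,
                           beam_width_um=5.0, photons_per_line=500,
                           seed=4, seed_policy="per_line")
        assert not np.array_equal(b.image[:, 0], b.image[:, 1])

    def test_mirror_symmetry_in_expectation(self):
        """A laterally mirrored domain yields statistically mirrored total
        detected weight (3 sigma on matched independent runs)."""
        rng = np.random.default_rng(0)
        dims = (30, 10, 20)
        mus = np.tile(np.linspace(5.0, 25.0, dims[0])[:, None, None],
                      (1, dims[1], dims[2]))
        dom = m.VoxelDomain(mua=np.zeros(dims), mus=mus,
                            g=np.full(dims, 0.5), n=np.full(dims, 1.4),
                            voxel_size_um=5.0)
        dom_m = m.VoxelDomain(mua=dom.mua, mus=mus[::-1].copy(),
                              g=dom.g, n=dom.n, voxel_size_um=5.0)
        tg = m.TimeGrid(t_total_ps=2.4, dt_fs=24.0)
        x, xm = 30.0, 120.0  # mirrored source positions
        tot, tot_m = [], []
        for rep in range(8):
            s1 = m.McSource(x_um=x, y_um=25.0, width_um=5.0,
                            photon_count=4000, seed=100 + rep)
            s2 = m.McSource(x_um=xm, y_um=25.0, width_um=5.0,
                            photon_count=4000, seed=200 + rep)
            r1, _ = m.simulate(dom, s1, tg, na=0.5)
            r2, _ = m.simulate(dom_m, s2, tg, na=0.5)
            tot.append(m.extract_mc_ascan(r1, tg, na=0.5).flux.sum())
            tot_m.append(m.extract_mc_ascan(r2, tg, na=0.5).flux.sum())
        tot, tot_m = np.asarray(tot), np.asarray(tot_m)
        diff = tot.mean() - tot_m.mean()
        se = np.sqrt(tot.var(ddof=1) / 8 + tot_m.var(ddof=1) / 8)
        assert abs(diff) < 3.0 * max(se, 1e-12)
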