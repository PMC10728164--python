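"""Mason-Schamps conversions, CCS-charge regression and mobilogram
conformer summaries."""

import math

import numpy as np
import pytest

from ntdms.errors import ConfigurationError
from ntdms.mobility import (CCSValue, GasParameters, MobilityMeasurement,
                            ccs_charge_fit, ccs_from_mobility,
                            mobility_from_ccs, summarize_mobilogram,
                            Mobilogram, DA_TO_KG)
from ntdms.simulate import GeneratorConfig, egta_series, generate_mobilogram


class TestMasonSchamps:
    def test_roundtrip_identity(self):
        g = GasParameters()
        for ccs in (1853.0, 3623.0, 4880.0):
            mm = mobility_from_ccs(CCSValue(ccs=ccs, charge=20), 77136.0, g)
            back = ccs_from_mobility(mm, g)
            assert back.ccs == pytest.approx(ccs, rel=1e-9)

    def test_complex_anchor_mobility_in_tims_range(self):
        # the 1/K0 implied by the intact-complex CCS lies in the locked
        # 1.05-1.55 V s/cm^2 scan range
        mm = mobility_from_ccs(CCSValue(ccs=4880.0, charge=20), 77136.0)
        assert 1.05 < mm.inverse_K0 < 1.55

    def test_independent_arithmetic_oracle_six_sig_figs(self):
        # constant-by-constant evaluation at z=1, K0=1 cm^2/(V s), with the
        # heavy-ion limit where the reduced mass equals the gas mass
        g = GasParameters()
        M_kg = 28.0134 * 1.66053906660e-27
        prefactor = (3.0 / 16.0) * math.sqrt(
            2.0 * math.pi / (M_kg * 1.380649e-23 * 305.0))
        expected_m2 = prefactor * 1.602176634e-19 / (2.68678e25 * 1e-4)
        expected_A2 = expected_m2 * 1e20
        got = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=1.0, charge=1, ion_mass=1e9), g).ccs
        assert got == pytest.approx(expected_A2, rel=1e-6)

    def test_scaling_laws(self):
        g = GasParameters()
        base = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=1.2, charge=10, ion_mass=50000.0), g)
        double_z = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=1.2, charge=20, ion_mass=50000.0), g)
        assert double_z.ccs == pytest.approx(2 * base.ccs, rel=1e-12)
        double_invk0 = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=2.4, charge=10, ion_mass=50000.0), g)
        assert double_invk0.ccs == pytest.approx(2 * base.ccs, rel=1e-12)
        hot = GasParameters(temperature=4 * 305.0)
        half = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=1.2, charge=10, ion_mass=50000.0), hot)
        assert half.ccs == pytest.approx(base.ccs / 2, rel=1e-12)

    def test_reduced_mass_heavy_ion_limit(self):
        g = GasParameters()
        heavy = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=1.0, charge=1, ion_mass=5e6), g).ccs
        M_kg = g.gas_mass * DA_TO_KG
        closed = (3 / 16) * math.sqrt(2 * math.pi /
                                      (M_kg * g.kb * g.temperature)) * \
            g.e / (g.N0 * 1e-4) * 1e20
        assert heavy == pytest.approx(closed, rel=1e-4)

    def test_mobility_halving_ccs_doubles_k0(self):
        a = mobility_from_ccs(CCSValue(ccs=4000.0, charge=15), 70000.0)
        b = mobility_from_ccs(CCSValue(ccs=2000.0, charge=15), 70000.0)
        assert b.inverse_K0 == pytest.approx(a.inverse_K0 / 2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            MobilityMeasurement(inverse_K0=-1.0, charge=10, ion_mass=1000.0)
        with pytest.raises(ConfigurationError):
            CCSValue(ccs=-5.0, charge=10)


class TestCcsChargeFit:
    def test_collinear_exact(self):
        pts = [(z, 100.0 + 25.0 * z) for z in (6, 7, 8, 9)]
        slope, intercept, r2 = ccs_charge_fit(pts)
        assert slope == pytest.approx(25.0)
        assert intercept == pytest.approx(100.0)
        assert r2 == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        slope, intercept, r2 = ccs_charge_fit([(18, 4800.0), (21, 4950.0)])
        assert slope == pytest.approx(50.0)
        assert r2 == pytest.approx(1.0)

    def test_symmetric_noise_unbiased(self):
        rng = np.random.default_rng(12)
        slopes = []
        for _ in range(300):
            z = np.arange(15, 22)
            ccs = 1000.0 + 30.0 * z + rng.normal(0, 10.0, z.size)
            slope, _, _ = ccs_charge_fit(list(zip(z, ccs)))
            slopes.append(slope)
        assert np.mean(slopes) == pytest.approx(30.0, rel=0.01)

    def test_degenerate_charges_rejected(self):
        with pytest.raises(ConfigurationError):
            ccs_charge_fit([(20, 4800.0), (20, 4810.0)])


class TestMobilogramSummary:
    def test_single_conformer_anchor(self):
        mob, truth = generate_mobilogram([(4880.0, 1.0, 40.0)], 20, 77136.0,
                                         c=GeneratorConfig(seed=1))
        confs = summarize_mobilogram(mob)
        assert len(confs) == 1
        assert confs[0].apex_ccs == pytest.approx(4880.0, rel=1e-3)
        assert confs[0].share == pytest.approx(1.0)

    def test_separated_gaussians_shares(self):
        mob, _ = generate_mobilogram(
            [(4000.0, 0.5, 30.0), (5000.0, 0.5, 30.0)], 20, 77136.0,
            c=GeneratorConfig(seed=2))
        confs = summarize_mobilogram(mob)
        assert len(confs) == 2
        for c in confs:
            assert c.share == pytest.approx(0.5, abs=0.02)

    def test_three_weighted_conformers(self):
        weights = (0.6, 0.3, 0.1)
        mob, _ = generate_mobilogram(
            [(4000.0, weights[0], 25.0), (4600.0, weights[1], 25.0),
             (5200.0, weights[2], 25.0)], 20, 77136.0,
            c=GeneratorConfig(seed=3))
        confs = summarize_mobilogram(mob)
        assert [round(c.share, 1) for c in confs] == [0.6, 0.3, 0.1]

    def test_merged_peaks_below_prominence_report_one(self):
        mob, _ = generate_mobilogram(
            [(4800.0, 0.5, 60.0), (4840.0, 0.5, 60.0)], 20, 77136.0,
            c=GeneratorConfig(seed=4))
        confs = summarize_mobilogram(mob, min_prominence=0.2)
        assert len(confs) == 1

    def test_shares_invariant_under_rescaling(self):
        mob, _ = generate_mobilogram(
            [(4000.0, 0.7, 30.0), (5000.0, 0.3, 30.0)], 20, 77136.0,
            c=GeneratorConfig(seed=5))
        c1 = summarize_mobilogram(mob)
        mob.intensity = mob.intensity * 137.0
        c2 = summarize_mobilogram(mob)
        assert [c.share for c in c1] == pytest.approx([c.share for c in c2])

    def test_flat_mobilogram_empty(self):
        mob = Mobilogram(np.linspace(1.0, 1.5, 100), np.ones(100),
                         charge=20, ion_mass=77136.0)
        assert summarize_mobilogram(mob) == []

    def test_egta_series_conformer_counts_nondecreasing(self):
        counts = [len(summarize_mobilogram(m))
                  for m, _ in egta_series(seed=6)]
        assert counts == sorted(counts)
        assert counts[0] == 1
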