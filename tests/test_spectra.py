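"""Isotope envelopes, charge inference, deconvolution and quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntdms.chem import ISOTOPE_SPACING, PROTON_MASS, mz_of
from ntdms.errors import ConfigurationError
from ntdms.spectra import (PickerSettings, Spectrum, centroid, deconvolve,
                           envelope_fit_score, infer_charge, isotope_envelope,
                           quantify, DeconvolvedSpecies, _ISOTOPES,
                           AVERAGINE_COMPOSITION, averagine_formula)


class TestIsotopeEnvelope:
    def test_single_carbon(self):
        env = isotope_envelope({"C": 1}, model="elemental")
        assert env.probabilities == pytest.approx([0.9893, 0.0107])
        assert env.offsets == pytest.approx([0.0, 1.00336], abs=1e-5)

    @given(st.integers(1, 400), st.integers(0, 50), st.integers(0, 4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_probabilities_normalized(self, nc, nn, ns):
        env = isotope_envelope({"C": nc, "N": nn, "S": ns}, model="elemental")
        assert env.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(env.probabilities >= 0)

    def test_offsets_near_integer_spacing(self):
        env = isotope_envelope(18000.0)
        spacings = np.diff(env.offsets)
        assert np.all(np.abs(spacings - ISOTOPE_SPACING) < 0.01)

    def test_averagine_77kda_apex_offset(self):
        # oracle: analytic mean neutron surplus of the scaled formula
        formula = averagine_formula(77136.0)
        mean = sum(cnt * sum(k * ab for k, _, ab in _ISOTOPES[el]) /
                   sum(ab for _, _, ab in _ISOTOPES[el])
                   for el, cnt in formula.items())
        env = isotope_envelope(77136.0)
        apex = env.most_probable_offset()
        assert apex > 40.0
        assert apex == pytest.approx(mean * ISOTOPE_SPACING, abs=2.5)

    def test_unknown_element_rejected(self):
        with pytest.raises(ConfigurationError):
            isotope_envelope({"Xx": 3}, model="elemental")

    def test_truncation_bounds(self):
        with pytest.raises(ConfigurationError):
            isotope_envelope(5000.0, truncation=0.0)


class TestInferCharge:
    @pytest.mark.parametrize("spacing,z", [
        (0.05276, 19),      # intact-complex isotope spacing
        (1.00235, 1),
        (0.125, 8),         # TnC monomer isolation charge
    ])
    def test_known_spacings(self, spacing, z):
        cluster = 2000.0 + spacing * np.arange(6)
        assert infer_charge(cluster) == z

    def test_irregular_spacing_no_call(self):
        assert infer_charge([100.0, 100.5, 102.5, 102.6]) is None

    def test_too_few_peaks(self):
        with pytest.raises(ConfigurationError):
            infer_charge([100.0, 100.1])

    def test_recovers_charge_under_jitter(self):
        rng = np.random.default_rng(7)
        for z in range(1, 26):
            spacing = ISOTOPE_SPACING / z
            gaps = spacing * (1.0 + rng.uniform(-0.05, 0.05, size=11))
            cluster = 3000.0 + np.concatenate([[0.0], np.cumsum(gaps)])
            assert infer_charge(cluster) == z


class TestFitScore:
    def test_true_mass_beats_off_by_one_isotope(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mass = float(rng.uniform(10_000, 80_000))
            z = int(rng.integers(6, 22))
            env = isotope_envelope(mass)
            mzs = (mass + env.offsets + z * PROTON_MASS) / z
            peaks = Spectrum(mzs, env.probabilities * 1e6,
                             {"centroided": True})
            true_score = envelope_fit_score(peaks, z, mass)
            up = envelope_fit_score(peaks, z, mass + ISOTOPE_SPACING)
            down = envelope_fit_score(peaks, z, mass - ISOTOPE_SPACING)
            assert true_score > up and true_score > down


class TestDeconvolve:
    def test_noiseless_mixture_roundtrip(self, tnc_mixture_deconvolved):
        species, truth = tnc_mixture_deconvolved
        true_masses = [t["mass"] for t in truth.species]
        assert len(species) == len(true_masses)
        for sp in species:
            err = min(abs(sp.monoisotopic_mass - m) / m * 1e6
                      for m in true_masses)
            assert err < 2.0
            assert sp.fit_score > 0.99

    def test_abundance_ranks_follow_proportions(self, tnc_mixture_deconvolved):
        species, truth = tnc_mixture_deconvolved
        # 2-Ca most abundant, 3-Ca least
        by_abundance = sorted(species, key=lambda s: -s.abundance)
        truth_by_mass = {round(t["mass"]): t["proportion"]
                         for t in truth.species}
        props = [truth_by_mass[round(sp.monoisotopic_mass)]
                 for sp in by_abundance]
        assert props[0] == 0.5 and props[-1] == 0.1

    def test_empty_and_zero_spectra(self):
        assert deconvolve(Spectrum(np.array([]), np.array([]))) == []
        s = Spectrum(np.linspace(1000, 1010, 500), np.zeros(500))
        assert deconvolve(s) == []

    def test_pure_noise_below_threshold_yields_nothing(self):
        rng = np.random.default_rng(0)
        mz = np.linspace(2000, 2100, 20000)
        noise = np.clip(50.0 * rng.standard_normal(mz.size), 0, None)
        assert deconvolve(Spectrum(mz, noise)) == []

    def test_profile_centroiding_recovers_peak_positions(self):
        mz = np.arange(1000.0, 1002.0, 0.001)
        mu = 1000.7321
        y = 1e4 * np.exp(-0.5 * ((mz - mu) / 0.01) ** 2)
        c = centroid(Spectrum(mz, y))
        assert len(c) == 1
        assert c.mz[0] == pytest.approx(mu, abs=1e-4)


class TestQuantify:
    def _mk(self, abundances):
        return [DeconvolvedSpecies(monoisotopic_mass=1000.0 + i, charge=1,
                                   abundance=a, fit_score=1.0, snr=10.0)
                for i, a in enumerate(abundances)]

    def test_paper_proportions(self):
        props = quantify(self._mk([2, 2, 5, 1]))
        assert sorted(props.values()) == pytest.approx([0.1, 0.2, 0.2, 0.5])

    def test_single_species(self):
        assert list(quantify(self._mk([42.0])).values()) == [1.0]

    def test_equal_abundances(self):
        assert list(quantify(self._mk([3, 3, 3, 3])).values()) == \
            pytest.approx([0.25] * 4)

    def test_permutation_invariant_and_sums_to_one(self):
        species = self._mk([5, 1, 3, 2])
        labels = ["a", "b", "c", "d"]
        p1 = quantify(species, labels)
        p2 = quantify(species[::-1], labels[::-1])
        assert p1 == p2
        assert sum(p1.values()) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(Exception):
            quantify(self._mk([0.0, 0.0]))
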