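"""b/y fragment masses, MS2 matching, adduct-interval localization and
bond-cleavage coverage."""

import numpy as np
import pytest
from pyteomics import mass as pmass

import ntdms as n
from ntdms.errors import ConfigurationError, DataInconsistencyError
from ntdms.fragments import (AdductEvidence, FragmentIon, bond_coverage,
                             evidence_from_matches, fragment_mass,
                             localize_adducts, make_ion, match_fragments,
                             theoretical_ions)
from ntdms.simulate import GeneratorConfig, generate_ms2
from ntdms.spectra import Spectrum
from ntdms import fixtures as fx
from conftest import random_sequence


def pform(seq, n_ca=0):
    return n.Proteoform(sequence=n.ProteinSequence("x", seq),
                        adducts=n.MetalAdduct(count=n_ca))


class TestFragmentMass:
    def test_y1_lysine_oracle(self):
        # elemental oracle: y1 of ...K is the Lys residue plus water
        oracle = pmass.calculate_mass(sequence="K")
        assert fragment_mass(pform("ACDEFGK"), "y", 1) == pytest.approx(
            oracle, abs=1e-6)

    def test_by_complementarity_unmodified(self):
        p = pform("MDDIYKAAVEQLTEE")
        total = n.neutral_mass(p)
        L = 15
        for i in range(1, L):
            s = fragment_mass(p, "b", i) + fragment_mass(p, "y", L - i)
            assert s == pytest.approx(total, abs=1e-9)

    def test_by_complementarity_with_adducts_partitioned(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = random_sequence(rng, 30)
            p = pform(seq, 2)
            sites = sorted(rng.choice(np.arange(1, 31), size=2, replace=False))
            total = n.neutral_mass(p)
            for i in range(1, 30):
                nb = sum(1 for q in sites if q <= i)
                s = fragment_mass(p, "b", i, nb) + \
                    fragment_mass(p, "y", 30 - i, 2 - nb)
                assert s == pytest.approx(total, abs=1e-9)

    def test_y16_spans_final_residues(self, tnc_seq):
        # y16 of the 161-residue chain covers 146..161, past both
        # C-terminal structural Ca sites
        ion = make_ion(fx.tnc_proteoform(0), "y", 16)
        tail = tnc_seq.slice(146, 161)
        oracle = pmass.calculate_mass(sequence=tail)
        assert ion.neutral_mass == pytest.approx(oracle, abs=1e-6)

    def test_out_of_span_modification_rejected(self):
        with pytest.raises(ConfigurationError):
            fragment_mass(pform("ACSDEFG"), "b", 2, phospho_positions=[5])


class TestMatchFragments:
    def test_roundtrip_all_matched_below_1ppm(self):
        p = pform("MDDIYKAAVEQLTEEQKNEFKAAFDIFVLG", 1)
        spec, truth = generate_ms2(p, [3], 1.0, GeneratorConfig(seed=4))
        theo = theoretical_ions(p, max_adducts=1, charges=(1, 2))
        matches = match_fragments(spec, theo)
        assert len(matches) == len(spec)
        assert all(abs(m.ppm_error) < 1.0 for m in matches)

    def test_displaced_peak_unmatched(self):
        p = pform("ACDEFGHIK")
        ion = make_ion(p, "b", 4)
        peak = Spectrum(np.array([ion.theoretical_mz * (1 + 30e-6)]),
                        np.array([100.0]), {"centroided": True})
        assert match_fragments(peak, [ion]) == []

    def test_nearest_ion_wins(self):
        p = pform("ACDEFGHIK")
        a = make_ion(p, "b", 4)
        close = FragmentIon(series="y", index=3, charge=1,
                            theoretical_mz=a.theoretical_mz * (1 + 8e-6))
        peak = Spectrum(np.array([a.theoretical_mz * (1 + 2e-6)]),
                        np.array([9.0]), {"centroided": True})
        matches = match_fragments(peak, [a, close])
        # brute-force nearest-neighbour oracle: |2| < |6|
        assert len(matches) == 1 and matches[0].ion.series == "b"


class TestLocalization:
    def test_paper_evidence_sets(self, tnc_seq):
        expected = {"domain_II": (68, 76, 73, 76, "DFDE"),
                    "domain_III": (110, 115, 113, 115, "DLD"),
                    "domain_IV": (141, 145, 141, 145, "DKNND")}
        meta = fx.ca_evidence_metadata()
        for name, ev in fx.ca_evidence().items():
            ivs = localize_adducts(ev, tnc_seq,
                                   total_adducts=meta["sets"][name]["total_adducts"])
            best = min(ivs, key=lambda iv: iv.trimmed_end - iv.trimmed_start)
            r0, r1, t0, t1, motif = expected[name]
            assert (best.raw_start, best.raw_end) == (r0, r1)
            assert (best.trimmed_start, best.trimmed_end) == (t0, t1)
            assert best.motif == motif

    def test_adjacent_increment_single_residue(self, tnc_seq):
        ev = AdductEvidence(ions=(
            FragmentIon(series="b", index=112, adduct_count=0),
            FragmentIon(series="b", index=113, adduct_count=1)),
            chain_length=161)
        iv = localize_adducts(ev, tnc_seq)[0]
        assert iv.raw_start == iv.raw_end == 113

    def test_no_acidic_residue_flagged_untrimmed(self):
        seq = n.ProteinSequence("x", "GGGGGGGGGG")
        ev = AdductEvidence(ions=(
            FragmentIon(series="b", index=3, adduct_count=0),
            FragmentIon(series="b", index=6, adduct_count=1)),
            chain_length=10)
        iv = localize_adducts(ev, seq)[0]
        assert not iv.trimmed
        assert (iv.raw_start, iv.raw_end) == (4, 6)

    def test_empty_intersection_raises(self, tnc_seq):
        ev = AdductEvidence(ions=(
            FragmentIon(series="b", index=50, adduct_count=1),
            FragmentIon(series="y", index=50, adduct_count=1)),
            chain_length=161)
        # b says site <= 50; y says site >= 112
        with pytest.raises(DataInconsistencyError):
            localize_adducts(ev, tnc_seq, total_adducts=1)

    def test_nonmonotone_evidence_raises(self, tnc_seq):
        ev = AdductEvidence(ions=(
            FragmentIon(series="b", index=50, adduct_count=2),
            FragmentIon(series="b", index=60, adduct_count=1)),
            chain_length=161)
        assert ev.violations
        with pytest.raises(DataInconsistencyError):
            localize_adducts(ev, tnc_seq)

    def test_interval_never_widens_with_more_evidence(self, tnc_seq):
        base = (FragmentIon(series="b", index=90, adduct_count=0),
                FragmentIon(series="b", index=130, adduct_count=1))
        ev1 = AdductEvidence(ions=base, chain_length=161)
        iv1 = localize_adducts(ev1, tnc_seq, total_adducts=1)[0]
        extra = base + (FragmentIon(series="y", index=52, adduct_count=1),
                        FragmentIon(series="y", index=40, adduct_count=0))
        ev2 = AdductEvidence(ions=extra, chain_length=161)
        iv2 = localize_adducts(ev2, tnc_seq, total_adducts=1)[0]
        assert iv2.raw_start >= iv1.raw_start
        assert iv2.raw_end <= iv1.raw_end

    def test_localization_sound_on_random_synthetics(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(30):
            L = int(rng.integers(30, 70))
            seq = random_sequence(rng, L)
            k = int(rng.integers(1, 4))
            sites = sorted(rng.choice(np.arange(1, L + 1), size=k,
                                      replace=False).tolist())
            p = pform(seq, k)
            spec, _ = generate_ms2(p, sites, 1.0,
                                   GeneratorConfig(seed=int(rng.integers(2**31))))
            theo = theoretical_ions(p, max_adducts=k, charges=(1, 2))
            ev = evidence_from_matches(match_fragments(spec, theo), L)
            ivs = localize_adducts(ev, n.ProteinSequence("x", seq),
                                   total_adducts=k)
            for iv, site in zip(ivs, sites):
                assert iv.raw_start <= site <= iv.raw_end
                if seq[site - 1] in "DE":
                    assert iv.trimmed_start <= site <= iv.trimmed_end
                hits += 1
        assert hits >= 30


class TestBondCoverage:
    def _matches(self, p, bonds, L):
        out = []
        for j in bonds:
            out.append(make_ion(p, "b", j) if j % 2 else make_ion(p, "y", L - j))
        return out

    def test_full_coverage(self):
        p = pform("ACDEFGHIKL")
        assert bond_coverage(self._matches(p, range(1, 10), 10), 10).percent == 100.0

    def test_empty(self):
        assert bond_coverage([], 161).percent == 0.0

    def test_tnc_scale_example(self, tnc_seq):
        p = fx.tnc_proteoform(0)
        bonds = list(range(1, 102))       # 101 of 160 bonds
        rep = bond_coverage(self._matches(p, bonds, 161), 161)
        assert rep.cleaved_bonds == 101
        assert rep.percent == 63.1

    def test_agrees_with_bruteforce_counting(self):
        rng = np.random.default_rng(9)
        p = pform(random_sequence(rng, 40))
        for _ in range(50):
            bonds = rng.choice(np.arange(1, 40), size=rng.integers(0, 39),
                               replace=False)
            matches = self._matches(p, bonds.tolist(), 40)
            rep = bond_coverage(matches, 40)
            assert rep.cleaved_bonds == len(set(bonds.tolist()))
            assert rep.percent == round(100 * len(set(bonds.tolist())) / 39, 1)
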