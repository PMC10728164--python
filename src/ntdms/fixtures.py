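"""Packaged reference fixtures for the cardiac troponin system.

The TnC chain (UniProt P63316, 161 residues) ships as a FASTA fixture; its
three Ca2+ binding regions are bracketed by the packaged CAD evidence-ion
sets.  The cTnI and cTnT chains enter only through their measured subunit
masses, so grammars involving them use fixed-mass pseudo-subunits whose
base masses are chosen to be consistent with the measured assembly masses
(synthetic stand-ins, labelled as such; they carry no sequence information).

The intact-complex composition list is figure-derived: the four assigned
heterotrimer compositions are itemized in figure annotations rather than in
running text, so the shipped list is flagged accordingly.
"""

from __future__ import annotations

import json
from importlib import resources

from .chem import (AssemblySpecies, CompositionGrammar, FixedMassSubunit,
                   MetalAdduct, MOD_REGISTRY, Proteoform, ProteinSequence,
                   PseudoProteoform, SubunitGrammar, enumerate_candidates,
                   neutral_mass, CA_CHARGE_DISPLACEMENT)
from .fragments import AdductEvidence, FragmentIon
from .io import read_fasta

#: measured masses (Da) used as bookkeeping inputs
COMPLEX_MASS = 77136.0        # most abundant intact heterotrimer
DIMER_MASS = 42556.0          # ejected cTn(I-C) dimer
CTNT_MASS = 34580.0           # ejected cTnT monomer (mono-phosphorylated)
TNC_EJECTED_MASS = 18520.0    # ejected TnC monomer

#: charge-state windows (m/z) the species appear in
COMPLEX_WINDOW_Z19 = (4050.0, 4080.0)
TNC_WINDOW = (2600.0, 3100.0)

#: CCS anchor for the intact complex (A^2), measured in N2
COMPLEX_CCS = 4880.0

_PHOS = MOD_REGISTRY["phosphorylation"].mono_delta
_LYS_RESIDUE = 128.09496


def _data(name: str):
    return resources.files("ntdms.data").joinpath(name)


def tnc_sequence() -> ProteinSequence:
    """Human cardiac TnC, full UniProt numbering (Met1 = position 1)."""
    seq = read_fasta(_data("tnnc1_P63316.fasta"))
    return ProteinSequence(identifier="TnC", residues=seq.residues,
                           numbering_origin=1)


def tnc_proteoform(n_ca: int = 0,
                   mode: str = "charge-displacement") -> Proteoform:
    return Proteoform(sequence=tnc_sequence(),
                      adducts=MetalAdduct(count=n_ca, mode=mode))


def ca_evidence() -> dict[str, AdductEvidence]:
    """The three CAD evidence-ion sets localizing Ca2+ on TnC."""
    raw = json.loads(_data("ca_evidence.json").read_text())
    out = {}
    for name, entry in raw["sets"].items():
        ions = tuple(FragmentIon(series=i["series"], index=i["index"],
                                 adduct_count=i["adduct_count"])
                     for i in entry["ions"])
        out[name] = AdductEvidence(ions=ions,
                                   chain_length=raw["chain_length"])
    return out


def ca_evidence_metadata() -> dict:
    return json.loads(_data("ca_evidence.json").read_text())


# ---------------------------------------------------------------------------
# pseudo-subunits (sequence unavailable; base masses synthetic, anchored to
# the measured assembly masses so the bookkeeping is internally consistent)


def pseudo_ctni() -> FixedMassSubunit:
    """Unmodified cTnI stand-in: mass chosen so that bis-phosphorylated
    cTnI + (TnC + 3 Ca) reproduces the measured 42556 Da dimer."""
    tnc3ca = neutral_mass(tnc_proteoform(3))
    return FixedMassSubunit(mass=DIMER_MASS - tnc3ca - 2 * _PHOS, label="cTnI")


def pseudo_ctnt() -> FixedMassSubunit:
    """Unmodified cTnT stand-in: mono-phosphorylated form is 34580 Da."""
    return FixedMassSubunit(mass=CTNT_MASS - _PHOS, label="cTnT")


def dimer_grammar() -> CompositionGrammar:
    """Ejected cTn(I-C) dimer: cTnI phospho 0-2 x TnC Ca 2-3 (6 species)."""
    return CompositionGrammar(subunits=(
        SubunitGrammar(sequence=pseudo_ctni(), phospho_range=(0, 2)),
        SubunitGrammar(sequence=tnc_sequence(), ca_range=(2, 3)),
    ), label="cTn(I-C) dimer")


def tnc_grammar() -> CompositionGrammar:
    """Ejected TnC monomer: Ca occupancy 0-3 (4 species)."""
    return CompositionGrammar(subunits=(
        SubunitGrammar(sequence=tnc_sequence(), ca_range=(0, 3)),
    ), label="TnC monomer")


def ctnt_level_species() -> list[PseudoProteoform]:
    """Ejected cTnT isolation level: unmodified, mono-phosphorylated, and
    mono-phosphorylated with C-terminal Lys truncation (explicit list)."""
    base = pseudo_ctnt()
    phos = (MOD_REGISTRY["phosphorylation"], None)
    return [
        PseudoProteoform(base=base),
        PseudoProteoform(base=base, modifications=(phos,)),
        PseudoProteoform(base=base, modifications=(phos,),
                         truncation="[aa 1-286]",
                         truncation_delta=-_LYS_RESIDUE),
    ]


def intact_complex_species() -> list[AssemblySpecies]:
    """The four assigned intact heterotrimer compositions (figure-derived):
    mono-phosphorylated cTnT (full or C-terminally Lys-truncated) with
    mono- or bis-phosphorylated cTnI and TnC carrying 3 Ca2+."""
    ctni, ctnt = pseudo_ctni(), pseudo_ctnt()
    tnc3 = tnc_proteoform(3)
    phos = (MOD_REGISTRY["phosphorylation"], None)
    out = []
    for ni in (1, 2):
        for trunc in (False, True):
            subunits = (
                PseudoProteoform(base=ctni, modifications=(phos,) * ni),
                PseudoProteoform(base=ctnt, modifications=(phos,),
                                 truncation="[aa 1-286]" if trunc else None,
                                 truncation_delta=-_LYS_RESIDUE if trunc else 0.0),
                tnc3,
            )
            out.append(AssemblySpecies(subunits=subunits))
    return out


def isolation_levels() -> dict[str, list]:
    """Candidate species per isolation level of the complex-up experiment."""
    return {
        "complex": intact_complex_species(),
        "ejected_dimer": enumerate_candidates(dimer_grammar()),
        "ejected_cTnT": ctnt_level_species(),
        "ejected_TnC": enumerate_candidates(tnc_grammar()),
    }
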