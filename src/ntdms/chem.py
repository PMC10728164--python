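"""Exact-mass chemistry of proteoforms, metal adducts and non-covalent assemblies.

A *proteoform* is one molecular species of a protein: its backbone sequence
plus a concrete set of covalent modifications (acetylation, phosphorylation,
initiator-Met excision), non-covalent metal adducts (here Ca2+), and optional
terminal truncations.  Native MS of a folded complex preserves these species
intact, so assigning a native mass spectrum reduces to enumerating candidate
compositions and computing their exact neutral masses.

Residue masses and elemental compositions come from pyteomics; only the
adduct/assembly bookkeeping and the composition grammar are implemented here.

Two conventions for the mass of a bound divalent metal are supported:

``charge-displacement``
    The cation displaces two protons from acidic side chains:
    delta = m(40Ca) - 2 m(H+) = 39.96259 - 2 x 1.00728 = +37.94604 Da.
    This is the default, appropriate for native ESI of folded acidic proteins.
``neutral-addition``
    The neutral metal mass is simply added: +39.96259 Da.

All residue positions are expressed in full UniProt numbering (including the
initiator Met); Met excision changes mass only, never reported indices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

from pyteomics import mass as _pmass

from .errors import ConfigurationError, UnknownResidueError

# physical constants (Da)
PROTON_MASS = 1.007276
WATER_MONO = _pmass.calculate_mass(formula="H2O")            # 18.0105646...
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
CA_CHARGE_DISPLACEMENT = 37.94604   # 40Ca (39.96259) minus 2 protons
CA_NEUTRAL_ADDITION = 39.96259
# average spacing between adjacent isotopologue peaks of a peptide (Da)
ISOTOPE_SPACING = 1.00235

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

MassScale = Literal["monoisotopic", "average"]
AdductMode = Literal["charge-displacement", "neutral-addition"]

# std_aa_comp entries are residue (water-free) compositions
_MONO_RESIDUE = {aa: _pmass.calculate_mass(composition=comp)
                 for aa, comp in _pmass.std_aa_comp.items() if aa in CANONICAL_RESIDUES}
_AVG_RESIDUE = {aa: _pmass.calculate_mass(composition=comp, average=True)
                for aa, comp in _pmass.std_aa_comp.items() if aa in CANONICAL_RESIDUES}


def mz_of(mass: float, z: int) -> float:
    """m/z of a neutral mass carrying ``z`` protons: (M + z*1.007276)/z."""
    if z < 1:
        raise ConfigurationError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain with its position in full UniProt numbering.

    ``numbering_origin`` is the UniProt position of the first listed residue
    (1 for a full-length chain including Met1).
    """

    identifier: str
    residues: str
    numbering_origin: int = 1

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ConfigurationError("empty sequence")
        if self.numbering_origin < 1:
            raise ConfigurationError("numbering_origin must be >= 1")
        for i, aa in enumerate(self.residues):
            if aa not in CANONICAL_RESIDUES:
                raise UnknownResidueError(aa, self.numbering_origin + i)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_position(self) -> int:
        return self.numbering_origin + len(self.residues) - 1

    def slice(self, start: int, end: int) -> str:
        """Residue string for inclusive UniProt positions ``start..end``."""
        i = start - self.numbering_origin
        j = end - self.numbering_origin + 1
        if i < 0 or j > len(self.residues) or i >= j:
            raise ConfigurationError(
                f"positions {start}..{end} outside chain "
                f"{self.numbering_origin}..{self.last_position}")
        return self.residues[i:j]


@dataclass(frozen=True)
class Modification:
    """A named covalent modification with a fixed mass delta.

    ``site_rule`` restricts where it may sit: 'N-terminus', 'index' (a
    specific residue position), 'S/T/Y' or 'K'.
    """

    name: str
    mono_delta: float
    avg_delta: Optional[float] = None
    site_rule: str = "index"

    def delta(self, scale: MassScale) -> float:
        if scale == "average" and self.avg_delta is not None:
            return self.avg_delta
        return self.mono_delta


#: built-in modification registry (deltas in Da)
MOD_REGISTRY: dict[str, Modification] = {
    m.name: m for m in (
        Modification("acetylation", 42.01057, 42.0367, "N-terminus"),
        Modification("phosphorylation", 79.96633, 79.9799, "S/T/Y"),
        Modification("met1-excision",
                     -(_MONO_RESIDUE["M"]), -(_AVG_RESIDUE["M"]), "N-terminus"),
    )
}


def load_modification_registry(path) -> dict[str, Modification]:
    """Read a tab-separated registry table: name, mono_delta, avg_delta, site_rule."""
    registry: dict[str, Modification] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, mono, avg, rule = line.split("\t")
            registry[name] = Modification(name, float(mono), float(avg), rule)
    return registry


@dataclass(frozen=True)
class MetalAdduct:
    """``count`` bound metal ions (Ca) under a mass-accounting ``mode``."""

    element: str = "Ca"
    count: int = 0
    mode: AdductMode = "charge-displacement"
    max_count: int = 3

    def __post_init__(self):
        if self.element != "Ca":
            raise ConfigurationError(f"unsupported adduct element {self.element!r}")
        if not 0 <= self.count <= self.max_count:
            raise ConfigurationError(
                f"adduct count {self.count} outside 0..{self.max_count}")

    @property
    def per_adduct_delta(self) -> float:
        return (CA_CHARGE_DISPLACEMENT if self.mode == "charge-displacement"
                else CA_NEUTRAL_ADDITION)

    @property
    def total_delta(self) -> float:
        return self.count * self.per_adduct_delta


@dataclass(frozen=True)
class Proteoform:
    """One neutral molecular species of a protein chain.

    ``modifications`` is a tuple of ``(Modification, position)`` pairs where
    position is a full-numbering residue index, or ``None`` for a
    count-only (unlocalized) modification.  ``truncation`` is an inclusive
    position range removed from a terminus, e.g. C-terminal Lys.
    """

    sequence: ProteinSequence
    modifications: tuple = ()
    adducts: MetalAdduct = MetalAdduct()
    truncation: Optional[tuple[int, int]] = None
    label: Optional[str] = None

    def __post_init__(self):
        seen = set()
        lo, hi = self.retained_span
        for mod, pos in self.modifications:
            if pos is not None:
                if not lo <= pos <= hi:
                    raise ConfigurationError(
                        f"modification {mod.name} at {pos} outside retained "
                        f"span {lo}..{hi}")
                key = (mod.name, pos)
                if key in seen:
                    raise ConfigurationError(
                        f"duplicate modification {mod.name} at position {pos}")
                seen.add(key)
        if self.truncation is not None:
            t0, t1 = self.truncation
            s = self.sequence
            if not (t0 == s.numbering_origin or t1 == s.last_position):
                raise ConfigurationError(
                    "only terminal truncations are supported")

    @property
    def retained_span(self) -> tuple[int, int]:
        """Inclusive (first, last) retained positions in full numbering."""
        s = self.sequence
        lo, hi = s.numbering_origin, s.last_position
        if self.truncation is not None:
            t0, t1 = self.truncation
            if t0 == lo:
                lo = t1 + 1
            else:
                hi = t0 - 1
        return lo, hi

    @property
    def retained_residues(self) -> str:
        lo, hi = self.retained_span
        return self.sequence.slice(lo, hi)

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = [self.sequence.identifier]
        nph = sum(1 for m, _ in self.modifications if m.name == "phosphorylation")
        if nph:
            parts.insert(0, "p" * nph)
        if any(m.name == "acetylation" for m, _ in self.modifications):
            parts.append("ac")
        if self.adducts.count:
            parts.append(f"{self.adducts.count}Ca")
        if self.truncation:
            lo, hi = self.retained_span
            parts.append(f"[aa {lo}-{hi}]")
        return "+".join(parts)


def neutral_mass(p: Proteoform, scale: MassScale = "monoisotopic") -> float:
    """Neutral mass: residue sum + water + modification deltas + adduct deltas."""
    table = _MONO_RESIDUE if scale == "monoisotopic" else _AVG_RESIDUE
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
    total = water + sum(table[aa] for aa in p.retained_residues)
    total += sum(mod.delta(scale) for mod, _ in p.modifications)
    total += p.adducts.total_delta
    return total


@dataclass(frozen=True)
class AssemblySpecies:
    """A non-covalent multimer; its mass is the plain sum of subunit masses."""

    subunits: tuple
    label: str = ""

    def __post_init__(self):
        if len(self.subunits) == 0:
            raise ConfigurationError("assembly needs at least one subunit")

    def describe(self) -> str:
        return self.label or "/".join(s.describe() for s in self.subunits)


def assembly_mass(a: AssemblySpecies, scale: MassScale = "monoisotopic") -> float:
    """Sum of subunit neutral masses (no condensation loss).

    Uses exact float summation so the result is invariant under subunit
    reordering."""
    return math.fsum(neutral_mass(s, scale) for s in a.subunits)


@dataclass(frozen=True)
class FixedMassSubunit:
    """A subunit known only by its printed mass (sequence unavailable)."""

    mass: float
    label: str = ""

    def describe(self) -> str:
        return self.label or f"{self.mass:.0f} Da"


@dataclass(frozen=True)
class PseudoProteoform:
    """A proteoform of a subunit whose sequence is unavailable: a base mass
    plus modification/adduct deltas.  Used where only a printed subunit MW
    anchors the composition arithmetic."""

    base: FixedMassSubunit
    modifications: tuple = ()
    adducts: MetalAdduct = MetalAdduct()
    truncation: Optional[str] = None      # label of a named truncation
    truncation_delta: float = 0.0

    def mass(self, scale: MassScale = "monoisotopic") -> float:
        return (self.base.mass + sum(m.delta(scale) for m, _ in self.modifications)
                + self.adducts.total_delta + self.truncation_delta)

    def describe(self) -> str:
        parts = [self.base.describe()]
        nph = sum(1 for m, _ in self.modifications if m.name == "phosphorylation")
        if nph:
            parts.insert(0, "p" * nph)
        if self.adducts.count:
            parts.append(f"{self.adducts.count}Ca")
        if self.truncation:
            parts.append(self.truncation)
        return "+".join(parts)


def species_mass(obj, scale: MassScale = "monoisotopic") -> float:
    """Neutral mass of a Proteoform, PseudoProteoform, AssemblySpecies or
    FixedMassSubunit."""
    if isinstance(obj, Proteoform):
        return neutral_mass(obj, scale)
    if isinstance(obj, PseudoProteoform):
        return obj.mass(scale)
    if isinstance(obj, FixedMassSubunit):
        return obj.mass
    if isinstance(obj, AssemblySpecies):
        return math.fsum(species_mass(s, scale) for s in obj.subunits)
    raise ConfigurationError(f"cannot compute mass of {type(obj).__name__}")


@dataclass(frozen=True)
class SubunitGrammar:
    """Allowed composition ranges for one subunit of a candidate grammar.

    ``sequence`` may be a full ProteinSequence or, when only a printed mass
    is available for the subunit, a FixedMassSubunit (variants then become
    PseudoProteoforms and truncation options are ``(label, mass_delta)``).
    """

    sequence: object
    phospho_range: tuple[int, int] = (0, 0)
    ca_range: tuple[int, int] = (0, 0)
    acetylation_options: tuple[bool, ...] = (False,)
    met_excision_options: tuple[bool, ...] = (False,)
    truncation_options: tuple = (None,)  # entries: None or (name, (start, end))
    adduct_mode: AdductMode = "charge-displacement"

    def cardinality(self) -> int:
        n = (self.phospho_range[1] - self.phospho_range[0] + 1)
        n *= (self.ca_range[1] - self.ca_range[0] + 1)
        n *= len(self.acetylation_options) * len(self.met_excision_options)
        n *= len(self.truncation_options)
        return n

    def variants(self) -> list:
        out = []
        fixed_mass = isinstance(self.sequence, FixedMassSubunit)
        for nph in range(self.phospho_range[0], self.phospho_range[1] + 1):
            for nca in range(self.ca_range[0], self.ca_range[1] + 1):
                for ac in self.acetylation_options:
                    for mex in self.met_excision_options:
                        for trunc in self.truncation_options:
                            mods = []
                            if ac:
                                mods.append((MOD_REGISTRY["acetylation"], None))
                            if mex:
                                mods.append((MOD_REGISTRY["met1-excision"], None))
                            mods.extend((MOD_REGISTRY["phosphorylation"], None)
                                        for _ in range(nph))
                            adducts = MetalAdduct(count=nca, mode=self.adduct_mode,
                                                  max_count=max(3, nca))
                            if fixed_mass:
                                out.append(PseudoProteoform(
                                    base=self.sequence,
                                    modifications=tuple(mods), adducts=adducts,
                                    truncation=None if trunc is None else trunc[0],
                                    truncation_delta=0.0 if trunc is None
                                    else trunc[1]))
                            else:
                                out.append(Proteoform(
                                    sequence=self.sequence,
                                    modifications=tuple(mods), adducts=adducts,
                                    truncation=None if trunc is None else trunc[1],
                                ))
        return out


@dataclass(frozen=True)
class CompositionGrammar:
    """Cartesian-product grammar over one or more subunits.

    A single-subunit grammar enumerates Proteoforms; a multi-subunit grammar
    enumerates AssemblySpecies.
    """

    subunits: tuple[SubunitGrammar, ...]
    label: str = ""

    def cardinality(self) -> int:
        n = 1
        for s in self.subunits:
            n *= s.cardinality()
        return n


def _sort_key(species):
    if isinstance(species, (Proteoform, PseudoProteoform)):
        forms = (species,)
    else:
        forms = species.subunits
    key = []
    for p in forms:
        nph = sum(1 for m, _ in p.modifications if m.name == "phosphorylation")
        flags = tuple(sorted(m.name for m, _ in p.modifications
                             if m.name != "phosphorylation"))
        key.append((nph, p.adducts.count, flags, str(p.truncation or "")))
    return tuple(key)


def enumerate_candidates(g: CompositionGrammar, cap: int = 100_000) -> list:
    """Enumerate every composition the grammar allows, deduplicated and in
    deterministic lexicographic order of (phospho count, Ca count, flags).
    """
    size = g.cardinality()
    if size > cap:
        raise ConfigurationError(
            f"grammar enumerates {size} species, exceeding cap {cap}")
    per_subunit = [s.variants() for s in g.subunits]
    out: list = []
    seen = set()
    for combo in itertools.product(*per_subunit):
        species = combo[0] if len(combo) == 1 else AssemblySpecies(subunits=combo)
        k = _sort_key(species)
        if k in seen:
            continue
        seen.add(k)
        out.append(species)
    out.sort(key=_sort_key)
    return out
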