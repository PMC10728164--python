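"""b/y fragment masses, MS2 matching, and metal-adduct localization.

CAD of a protein carrying non-covalently bound metal ions produces b/y
fragments that, when adduct retention is position-faithful, carry exactly
the adducts whose binding residue lies within the fragment span.  Bracketing
the index at which the adduct count increments in each series, and
intersecting the b- and y-derived intervals, localizes each adduct to a
residue interval; clipping that interval to its first and last acidic
residue (D/E, the side chains with the highest Ca2+ affinity) gives the
reported binding motif.

All coordinates are 1-based, inclusive, in full UniProt numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import (PROTON_MASS, WATER_MONO, Proteoform, ProteinSequence,
                   mz_of, neutral_mass, _MONO_RESIDUE,
                   CA_CHARGE_DISPLACEMENT, CA_NEUTRAL_ADDITION, MOD_REGISTRY)
from .errors import ConfigurationError, DataInconsistencyError
from .spectra import Spectrum


@dataclass(frozen=True)
class FragmentIon:
    series: str                    # 'b' or 'y'
    index: int                     # number of residues in the fragment
    adduct_count: int = 0
    phospho_count: int = 0
    charge: int = 1
    theoretical_mz: float = 0.0
    neutral_mass: float = 0.0

    def __post_init__(self):
        if self.series not in ("b", "y"):
            raise ConfigurationError(f"unsupported ion series {self.series!r}")
        if self.index < 1:
            raise ConfigurationError("fragment index must be >= 1")


@dataclass
class FragmentMatch:
    ion: FragmentIon
    observed_mz: float
    ppm_error: float
    intensity: float


@dataclass
class AdductEvidence:
    """Observed adduct counts on b/y ions for one precursor proteoform.

    Within each series the counts must be non-decreasing with index; a
    violation is recorded in ``violations`` rather than silently dropped.
    """

    ions: tuple[FragmentIon, ...]
    chain_length: int
    violations: tuple = ()

    def __post_init__(self):
        viol = []
        for series in ("b", "y"):
            seq = sorted((i for i in self.ions if i.series == series),
                         key=lambda i: i.index)
            for a, b in zip(seq, seq[1:]):
                if b.adduct_count < a.adduct_count:
                    viol.append((a, b))
        self.violations = tuple(viol)

    @property
    def max_adduct_count(self) -> int:
        return max((i.adduct_count for i in self.ions), default=0)


@dataclass
class LocalizationInterval:
    adduct_ordinal: int            # k-th adduct counted from the N-terminus
    raw_start: int
    raw_end: int
    trimmed_start: int
    trimmed_end: int
    motif: str
    trimmed: bool = True
    binding_rank: Optional[int] = None  # energetic binding order, if known


@dataclass
class CoverageReport:
    cleaved_bonds: int
    total_bonds: int
    percent: float


def fragment_mass(p: Proteoform, series: str, index: int,
                  adduct_count: int = 0,
                  phospho_positions: Sequence[int] = ()) -> float:
    """Neutral mass of a b/y fragment with in-span modifications and adducts.

    b_i spans retained residues 1..i (no water); y_n spans the last n
    residues plus water.  Localized modifications on the proteoform are
    included automatically when they fall inside the span; explicit
    ``phospho_positions`` add phosphates at the given full-numbering
    positions, which must lie inside the span.
    """
    residues = p.retained_residues
    lo, hi = p.retained_span
    L = len(residues)
    if not 1 <= index < L:
        raise ConfigurationError(f"fragment index {index} outside 1..{L - 1}")
    if series == "b":
        span = (lo, lo + index - 1)
        mass = sum(_MONO_RESIDUE[a] for a in residues[:index])
    elif series == "y":
        span = (hi - index + 1, hi)
        mass = sum(_MONO_RESIDUE[a] for a in residues[L - index:]) + WATER_MONO
    else:
        raise ConfigurationError(f"unsupported ion series {series!r}")
    for mod, pos in p.modifications:
        if pos is None:
            # unlocalized mods on the precursor cannot be placed on fragments
            continue
        if span[0] <= pos <= span[1]:
            mass += mod.mono_delta
        elif mod.site_rule == "N-terminus" and series == "b":
            if pos <= span[1]:
                mass += mod.mono_delta
    for pos in phospho_positions:
        if not span[0] <= pos <= span[1]:
            raise ConfigurationError(
                f"phosphorylation at {pos} outside fragment span {span}")
        mass += MOD_REGISTRY["phosphorylation"].mono_delta
    per_ca = (CA_CHARGE_DISPLACEMENT
              if p.adducts.mode == "charge-displacement" else CA_NEUTRAL_ADDITION)
    return mass + adduct_count * per_ca


def make_ion(p: Proteoform, series: str, index: int, adduct_count: int = 0,
             charge: int = 1,
             phospho_positions: Sequence[int] = ()) -> FragmentIon:
    m = fragment_mass(p, series, index, adduct_count, phospho_positions)
    return FragmentIon(series=series, index=index, adduct_count=adduct_count,
                       phospho_count=len(phospho_positions), charge=charge,
                       theoretical_mz=mz_of(m, charge), neutral_mass=m)


def theoretical_ions(p: Proteoform, max_adducts: Optional[int] = None,
                     charges: Sequence[int] = (1,)) -> list[FragmentIon]:
    """All b/y ions over every bond, adduct count 0..max and given charges."""
    L = len(p.retained_residues)
    kmax = p.adducts.count if max_adducts is None else max_adducts
    out = []
    for series in ("b", "y"):
        for idx in range(1, L):
            for k in range(kmax + 1):
                for z in charges:
                    out.append(make_ion(p, series, idx, k, z))
    return out


def match_fragments(ms2_peaks: Spectrum, theoretical: Sequence[FragmentIon],
                    tolerance_ppm: float = 20.0) -> list[FragmentMatch]:
    """Greedy nearest-neighbour matching of MS2 peaks to theoretical ions.

    Candidate (peak, ion) pairs within tolerance are assigned in order of
    increasing |ppm|; each peak is used at most once and each ion matched at
    most once, so ties resolve deterministically to the smallest error.
    """
    if tolerance_ppm <= 0:
        raise ConfigurationError("tolerance must be > 0")
    theo = sorted(theoretical, key=lambda i: i.theoretical_mz)
    theo_mz = np.array([i.theoretical_mz for i in theo])
    pairs = []
    for pi, (mz, inten) in enumerate(zip(ms2_peaks.mz, ms2_peaks.intensity)):
        lo = np.searchsorted(theo_mz, mz * (1 - tolerance_ppm * 1e-6))
        hi = np.searchsorted(theo_mz, mz * (1 + tolerance_ppm * 1e-6))
        for ti in range(lo, hi):
            err = (mz - theo_mz[ti]) / theo_mz[ti] * 1e6
            pairs.append((abs(err), pi, ti, err, inten))
    pairs.sort(key=lambda t: (t[0], t[2]))
    used_peaks, used_ions, matches = set(), set(), []
    for _, pi, ti, err, inten in pairs:
        if pi in used_peaks or ti in used_ions:
            continue
        used_peaks.add(pi)
        used_ions.add(ti)
        matches.append(FragmentMatch(ion=theo[ti], observed_mz=float(ms2_peaks.mz[pi]),
                                     ppm_error=float(err), intensity=float(inten)))
    matches.sort(key=lambda m: (m.ion.series, m.ion.index, m.ion.adduct_count))
    return matches


def evidence_from_matches(matches: Sequence[FragmentMatch],
                          chain_length: int) -> AdductEvidence:
    """Reduce matched ions to one observed adduct count per (series, index),
    keeping the most intense assignment when several compete."""
    best: dict[tuple[str, int], FragmentMatch] = {}
    for m in matches:
        key = (m.ion.series, m.ion.index)
        if key not in best or m.intensity > best[key].intensity:
            best[key] = m
    ions = tuple(sorted((m.ion for m in best.values()),
                        key=lambda i: (i.series, i.index)))
    return AdductEvidence(ions=ions, chain_length=chain_length)


def _bracket_from_b(ions, k, L):
    """Position bounds for the k-th adduct from b-series counts."""
    lo, hi = 1, L
    for ion in ions:
        if ion.adduct_count <= k - 1:
            lo = max(lo, ion.index + 1)
        if ion.adduct_count >= k:
            hi = min(hi, ion.index)
    return lo, hi


def _bracket_from_y(ions, k, k_total, L):
    """Position bounds for the k-th adduct (from N-terminus) from y-series
    counts: y_n with c adducts means the first L-n residues hold k_total-c."""
    lo, hi = 1, L
    for ion in ions:
        c = ion.adduct_count
        if c >= k_total - k + 1:
            lo = max(lo, L - ion.index + 1)
        if c <= k_total - k:
            hi = min(hi, L - ion.index)
    return lo, hi


def localize_adducts(e: AdductEvidence, seq: ProteinSequence,
                     trim_to: frozenset = frozenset("DE"),
                     total_adducts: Optional[int] = None,
                     strict: bool = True) -> list[LocalizationInterval]:
    """Interval localization of each adduct from b/y count increments.

    For the k-th adduct (counted from the N-terminus) the b-series brackets
    its position between the largest index still carrying k-1 adducts and
    the smallest index carrying k; the y-series brackets it symmetrically in
    C-terminal coordinates.  The raw interval is the intersection; the
    trimmed interval clips it to its first and last acidic (D/E) residue.
    """
    if strict and e.violations:
        a, b = e.violations[0]
        raise DataInconsistencyError(
            f"adduct counts decrease with index: {a.series}{a.index} carries "
            f"{a.adduct_count} but {b.series}{b.index} carries {b.adduct_count}")
    L = e.chain_length
    if L != len(seq.residues):
        raise ConfigurationError("evidence chain length does not match sequence")
    k_total = e.max_adduct_count if total_adducts is None else total_adducts
    b_ions = [i for i in e.ions if i.series == "b"]
    y_ions = [i for i in e.ions if i.series == "y"]
    origin = seq.numbering_origin
    out = []
    for k in range(1, k_total + 1):
        blo, bhi = _bracket_from_b(b_ions, k, L)
        ylo, yhi = _bracket_from_y(y_ions, k, k_total, L)
        lo, hi = max(blo, ylo), min(bhi, yhi)
        if lo > hi:
            raise DataInconsistencyError(
                f"adduct {k}: b-interval {blo}..{bhi} and y-interval "
                f"{ylo}..{yhi} do not intersect")
        raw_start = origin + lo - 1
        raw_end = origin + hi - 1
        window = seq.slice(raw_start, raw_end)
        acidic = [i for i, aa in enumerate(window) if aa in trim_to]
        if acidic:
            t0 = raw_start + acidic[0]
            t1 = raw_start + acidic[-1]
            trimmed = True
        else:
            t0, t1, trimmed = raw_start, raw_end, False
        out.append(LocalizationInterval(
            adduct_ordinal=k, raw_start=raw_start, raw_end=raw_end,
            trimmed_start=t0, trimmed_end=t1,
            motif=seq.slice(t0, t1), trimmed=trimmed))
    return out


def bond_coverage(matches: Sequence, chain_length: int) -> CoverageReport:
    """Backbone bond cleavage coverage from matched fragments.

    The bond between residues j and j+1 counts as cleaved when any matched
    b_j or y_{L-j} exists; percent is rounded to 0.1.
    """
    if chain_length < 2:
        raise ConfigurationError("chain length must be >= 2")
    cleaved = set()
    for m in matches:
        ion = m.ion if hasattr(m, "ion") else m
        j = ion.index if ion.series == "b" else chain_length - ion.index
        if 1 <= j <= chain_length - 1:
            cleaved.add(j)
    total = chain_length - 1
    pct = round(100.0 * len(cleaved) / total, 1)
    return CoverageReport(cleaved_bonds=len(cleaved), total_bonds=total,
                          percent=pct)
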