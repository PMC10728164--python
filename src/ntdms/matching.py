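"""Match deconvolved masses to candidate compositions and audit
complex -> subunit mass conservation in complex-up experiments.

Context-dependent ppm tolerances follow intact-protein practice: 2 ppm for
intact complex assignments, 16 ppm for monomer isolation spectra, 20 ppm for
fragment ions.  A species matches at most one candidate (best |ppm| wins,
ties broken by lexicographic candidate label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem import species_mass
from .errors import ConfigurationError
from .spectra import DeconvolvedSpecies

#: default per-context mass tolerances (ppm)
TOLERANCE_PPM = {"intact": 2.0, "monomer": 16.0, "fragment": 20.0}


@dataclass
class MassMatch:
    species: DeconvolvedSpecies
    candidate: object
    candidate_label: str
    candidate_mass: float
    ppm_error: float
    level: Optional[str] = None


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def match_masses(species: Sequence[DeconvolvedSpecies], candidates: Sequence,
                 tolerance_ppm: float = 2.0,
                 scale: str = "monoisotopic") -> tuple[list[MassMatch],
                                                       list[DeconvolvedSpecies]]:
    """Best-match-wins assignment of deconvolved species to candidates.

    Returns ``(matches, unmatched)``.  Each species is assigned to the
    candidate minimizing |ppm error| when that error is within tolerance.
    """
    if tolerance_ppm <= 0:
        raise ConfigurationError("tolerance must be > 0")
    table = [(c.describe(), species_mass(c, scale), c) for c in candidates]
    matches, unmatched = [], []
    for sp in species:
        best = None
        for label, cmass, cand in table:
            err = ppm_error(sp.monoisotopic_mass, cmass)
            if abs(err) > tolerance_ppm:
                continue
            if best is None or (abs(err), label) < (abs(best.ppm_error),
                                                    best.candidate_label):
                best = MassMatch(sp, cand, label, cmass, err)
        if best is None:
            unmatched.append(sp)
        else:
            matches.append(best)
    return matches, unmatched


def nearest_candidate(mass: float, candidates: Sequence,
                      scale: str = "monoisotopic") -> tuple[object, str, float]:
    """The candidate nearest in ppm to ``mass`` regardless of tolerance —
    used to report, not force, assignments that no candidate explains."""
    if not candidates:
        raise ConfigurationError("no candidates")
    best = min(((c, c.describe(), ppm_error(mass, species_mass(c, scale)))
                for c in candidates), key=lambda t: (abs(t[2]), t[1]))
    return best


@dataclass
class EjectionLedger:
    """Mass-conservation record for one subunit-ejection event."""

    parent_mass: float
    product_masses: tuple[float, ...]
    residual_da: float
    residual_ppm: float
    consistent: bool


def check_ejection(parent_mass: float, product_masses: Sequence[float],
                   tolerance_ppm: float = 2.0) -> EjectionLedger:
    """Verify that ejected products account for the parent complex mass.

    The residual ``parent - sum(products)`` is reported in Da and in ppm of
    the parent; the ledger is consistent when |residual| is within tolerance.
    """
    if len(product_masses) == 0:
        raise ConfigurationError("need at least one product")
    if parent_mass <= 0 or any(m <= 0 for m in product_masses):
        raise ConfigurationError("masses must be positive")
    residual = parent_mass - sum(product_masses)
    rppm = residual / parent_mass * 1e6
    return EjectionLedger(
        parent_mass=float(parent_mass),
        product_masses=tuple(float(m) for m in product_masses),
        residual_da=float(residual), residual_ppm=float(rppm),
        consistent=abs(rppm) <= tolerance_ppm)


def proteoform_landscape(matches: Sequence[MassMatch],
                         levels: Sequence[str]) -> dict:
    """Distinct-species counts per isolation level and their total.

    Each match must carry an isolation-level tag (``level`` attribute or the
    parallel ``levels`` ordering of level names to tally).  Species are
    distinct by (level, candidate label): the same composition seen at two
    levels counts at each level, duplicates within a level count once.
    """
    per_level: dict[str, set] = {lv: set() for lv in levels}
    for m in matches:
        lv = m.level
        if lv is None:
            raise ConfigurationError(
                f"match for {m.candidate_label} lacks an isolation level tag")
        if lv not in per_level:
            per_level[lv] = set()
        per_level[lv].add(m.candidate_label)
    counts = {lv: len(s) for lv, s in per_level.items()}
    return {"per_level": counts, "total": sum(counts.values())}


def landscape_from_candidates(candidates_by_level: dict) -> dict:
    """Landscape table straight from enumerated candidate lists, one list
    per isolation level, with the same distinct-label set semantics as
    ``proteoform_landscape``."""
    counts = {lv: len({c.describe() for c in cands})
              for lv, cands in candidates_by_level.items()}
    return {"per_level": counts, "total": sum(counts.values())}
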