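"""Isotope-envelope computation and isotopically resolved deconvolution.

The deconvolution follows the SNAP idea: pick peaks, group them into
charge-coherent isotope clusters, fit a theoretical isotope envelope
(averagine for unknown compositions) and report the *monoisotopic* mass of
each species together with a fit score, a quality factor and a local S/N.

Species passing the quality-factor / S/N / intensity thresholds (defaults
0.4 / 3.0 / 500, the values used for intact-protein work on FTICR data) are
returned sorted by abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from pyteomics import mass as _pmass

from .chem import ISOTOPE_SPACING, PROTON_MASS
from .errors import ConfigurationError, DataInconsistencyError

# isotope table: element -> list of (neutron surplus, mass, abundance)
_ISOTOPES = {
    "H": [(0, 1.00782503, 0.999885), (1, 2.01410178, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.00335484, 0.0107)],
    "N": [(0, 14.00307401, 0.99636), (1, 15.00010890, 0.00364)],
    "O": [(0, 15.99491462, 0.99757), (1, 16.99913150, 0.00038),
          (2, 17.99916040, 0.00205)],
    "S": [(0, 31.97207069, 0.9499), (1, 32.97145850, 0.0075),
          (2, 33.96786683, 0.0425), (4, 35.96708088, 0.0001)],
    "P": [(0, 30.97376151, 1.0)],
    "Ca": [(0, 39.96259120, 0.96941), (2, 41.95861830, 0.00647),
           (3, 42.95876680, 0.00135), (4, 43.95548110, 0.02086),
           (6, 45.95369280, 0.00004), (8, 47.95253400, 0.00187)],
}

#: Senko averagine: average elemental composition per 111.1254 Da of peptide
AVERAGINE_COMPOSITION = {"C": 4.9384, "H": 7.7583, "N": 1.3577,
                         "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254

_PRUNE = 1e-12


@dataclass
class Spectrum:
    """A single mass spectrum: ascending m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ConfigurationError("mz and intensity must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ConfigurationError("m/z axis must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ConfigurationError("negative intensities")

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotope distribution relative to the monoisotopic mass.

    ``offsets[k]`` is the abundance-weighted mean mass excess of the
    isotopologues with k extra neutrons; probabilities sum to 1.
    """

    offsets: np.ndarray
    probabilities: np.ndarray

    def most_probable_offset(self) -> float:
        return float(self.offsets[int(np.argmax(self.probabilities))])


@dataclass
class DeconvolvedSpecies:
    monoisotopic_mass: float
    charge: int
    abundance: float
    fit_score: float
    snr: float
    quality_factor: float = 1.0
    flags: tuple = ()

    def __post_init__(self):
        if self.charge < 1:
            raise ConfigurationError("charge must be >= 1")
        if not 0.0 <= self.fit_score <= 1.0 + 1e-9:
            raise ConfigurationError("fit_score outside [0, 1]")


@dataclass(frozen=True)
class PickerSettings:
    quality_factor_threshold: float = 0.4
    snr_threshold: float = 3.0
    intensity_threshold: float = 500.0
    max_charge: int = 30
    merge_charge_states: bool = True

    def __post_init__(self):
        if min(self.quality_factor_threshold, self.snr_threshold,
               self.intensity_threshold) < 0:
            raise ConfigurationError("picker thresholds must be >= 0")


# ---------------------------------------------------------------------------
# isotope envelopes


def _convolve_dist(p1, m1, p2, m2):
    """Convolve two (probability, mass-moment) distributions over neutron count."""
    p = np.convolve(p1, p2)
    m = np.convolve(p1, m2) + np.convolve(m1, p2)
    keep = len(p)
    while keep > 1 and p[keep - 1] < _PRUNE * p.max():
        keep -= 1
    return p[:keep], m[:keep]


def _element_dist(element: str, n: int):
    """Aggregated neutron-count distribution of n atoms of one element,
    by exponentiation-by-squaring of the single-atom distribution."""
    iso = _ISOTOPES.get(element)
    if iso is None:
        raise ConfigurationError(f"unknown element symbol {element!r}")
    size = max(k for k, _, _ in iso) + 1
    p1 = np.zeros(size)
    m1 = np.zeros(size)
    base = iso[0][1]
    for k, mass_, ab in iso:
        p1[k] += ab
        m1[k] += ab * (mass_ - base)
    p, m = np.array([1.0]), np.array([0.0])
    while n:
        if n & 1:
            p, m = _convolve_dist(p, m, p1, m1)
        p1, m1 = _convolve_dist(p1, m1, p1, m1)
        n >>= 1
    return p, m


def averagine_formula(mass: float) -> dict[str, int]:
    """Scale the averagine average-residue composition to ``mass`` and round."""
    if mass <= 0:
        raise ConfigurationError("mass must be positive")
    scale = mass / AVERAGINE_MASS
    return {el: max(0, int(round(scale * n)))
            for el, n in AVERAGINE_COMPOSITION.items()}


def isotope_envelope(mass_or_formula, truncation: float = 0.9999,
                     model: str = "averagine") -> IsotopeEnvelope:
    """Aggregated isotope envelope of a formula or an averagine pseudo-protein.

    ``mass_or_formula`` is either a dict of element counts (model
    'elemental') or a neutral mass in Da (model 'averagine').  The envelope
    is truncated to cumulative probability ``truncation`` (most probable
    peaks first) and renormalized.
    """
    if not 0 < truncation <= 1:
        raise ConfigurationError("truncation must be in (0, 1]")
    if isinstance(mass_or_formula, dict):
        formula = mass_or_formula
        if not formula:
            raise ConfigurationError("empty formula")
    else:
        if model == "elemental":
            raise ConfigurationError("elemental model requires a formula dict")
        formula = averagine_formula(float(mass_or_formula))
    p, m = np.array([1.0]), np.array([0.0])
    for el, n in formula.items():
        if n:
            pe, me = _element_dist(el, int(n))
            p, m = _convolve_dist(p, m, pe, me)
    with np.errstate(invalid="ignore", divide="ignore"):
        offsets = np.where(p > 0, m / np.maximum(p, 1e-300), 0.0)
    # keep most-probable bins until the cumulative probability target is met
    order = np.argsort(p)[::-1]
    cum = np.cumsum(p[order])
    n_keep = int(np.searchsorted(cum, truncation * p.sum()) + 1)
    keep = np.sort(order[:min(n_keep, p.size)])
    p, offsets = p[keep], offsets[keep]
    return IsotopeEnvelope(offsets=offsets, probabilities=p / p.sum())


# ---------------------------------------------------------------------------
# peak picking


def centroid(s: Spectrum, intensity_floor: float = 0.0) -> Spectrum:
    """Centroid a profile spectrum: local maxima + 3-point parabolic
    interpolation of apex position and height."""
    y = s.intensity
    if len(s) < 3:
        return Spectrum(s.mz.copy(), s.intensity.copy(), dict(s.metadata))
    idx = np.where((y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:]) &
                   (y[1:-1] > intensity_floor))[0] + 1
    mzs, hts = [], []
    for i in idx:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            d = 0.5 * (y0 - y2) / denom
            d = float(np.clip(d, -0.5, 0.5))
        else:
            d = 0.0
        # local m/z spacing may be non-uniform; interpolate linearly
        left = s.mz[i] - s.mz[i - 1]
        right = s.mz[i + 1] - s.mz[i]
        mzs.append(s.mz[i] + d * (right if d > 0 else left))
        hts.append(y1 - 0.25 * (y0 - y2) * d)
    order = np.argsort(mzs)
    return Spectrum(np.asarray(mzs)[order], np.asarray(hts)[order],
                    dict(s.metadata, centroided=True))


def is_profile(s: Spectrum) -> bool:
    """Heuristic: profile spectra are dense (median spacing << isotope spacing)."""
    if len(s) < 10:
        return False
    if s.metadata.get("centroided"):
        return False
    return float(np.median(np.diff(s.mz))) < 0.02


def infer_charge(peak_cluster: Sequence[float], cv_limit: float = 0.20) -> Optional[int]:
    """Charge from the isotope spacing of a cluster of adjacent peaks.

    Returns ``round(1.00235 / median adjacent spacing)``, or ``None`` when
    the spacing is too irregular (coefficient of variation > ``cv_limit``).
    """
    mz = np.sort(np.asarray(peak_cluster, dtype=float))
    if mz.size < 3:
        raise ConfigurationError("need at least 3 peaks to infer charge")
    d = np.diff(mz)
    med = float(np.median(d))
    if med <= 0:
        return None
    if float(np.std(d) / med) > cv_limit:
        return None
    return int(round(ISOTOPE_SPACING / med))


def _local_noise(centroids: Spectrum, mz0: float, window: float = 5.0) -> float:
    """Noise scale: MAD of centroid intensities within +- window m/z."""
    sel = (centroids.mz >= mz0 - window) & (centroids.mz <= mz0 + window)
    vals = centroids.intensity[sel]
    if vals.size < 4:
        return 0.0
    med = np.median(vals)
    return float(1.4826 * np.median(np.abs(vals - med)))


def _nearest_peak(mz_arr, target, tol):
    i = np.searchsorted(mz_arr, target)
    best, bd = -1, tol
    for j in (i - 1, i):
        if 0 <= j < mz_arr.size:
            d = abs(mz_arr[j] - target)
            if d <= bd:
                best, bd = j, d
    return best


def _nearest_peaks(mz_arr, targets, tol):
    """Vectorized nearest-peak lookup: index per target or -1."""
    idx = np.searchsorted(mz_arr, targets)
    left = np.clip(idx - 1, 0, mz_arr.size - 1)
    right = np.clip(idx, 0, mz_arr.size - 1)
    dl = np.abs(mz_arr[left] - targets)
    dr = np.abs(mz_arr[right] - targets)
    best = np.where(dl <= dr, left, right)
    dist = np.minimum(dl, dr)
    return np.where(dist <= tol, best, -1)


_ENVELOPE_CACHE: dict = {}


def _cached_envelope(mass: float, truncation: float) -> IsotopeEnvelope:
    """Averagine envelopes vary slowly with mass; cache on a 25 Da grid."""
    key = (int(round(mass / 25.0)), truncation)
    env = _ENVELOPE_CACHE.get(key)
    if env is None:
        env = isotope_envelope(key[0] * 25.0, truncation=truncation)
        if len(_ENVELOPE_CACHE) > 4096:
            _ENVELOPE_CACHE.clear()
        _ENVELOPE_CACHE[key] = env
    return env


def _collect_cluster(mz_arr, ints, seed_idx, z, tol):
    """Indices of peaks on the 1.00235/z grid through the seed peak."""
    spacing = ISOTOPE_SPACING / z
    found = [seed_idx]
    for step in (1, -1):
        k = 1
        misses = 0
        while misses < 2:
            target = mz_arr[seed_idx] + step * k * spacing
            j = _nearest_peak(mz_arr, target, tol)
            if j >= 0 and j not in found and ints[j] > 0:
                found.append(j)
                misses = 0
            else:
                misses += 1
            k += 1
            if k > 300:
                break
    return sorted(found)


def _score_candidate(mz_arr, ints, z, env, mono, tol):
    """Cosine similarity between observed cluster and theoretical envelope
    placed at monoisotopic mass ``mono``; also the matched quality fraction."""
    pred = (mono + env.offsets + z * PROTON_MASS) / z
    hits = _nearest_peaks(mz_arr, pred, tol)
    obs = np.where(hits >= 0, ints[np.clip(hits, 0, None)], 0.0)
    used = [int(j) for j in np.unique(hits[hits >= 0])]
    theo = env.probabilities
    denom = np.linalg.norm(obs) * np.linalg.norm(theo)
    score = float(obs @ theo / denom) if denom > 0 else 0.0
    major = theo >= 0.01 * theo.max()
    qf = float(np.count_nonzero(obs[major] > 0) / max(1, np.count_nonzero(major)))
    return score, qf, used, obs


def envelope_fit_score(centroids: Spectrum, z: int, mono: float,
                       envelope_truncation: float = 0.99995) -> float:
    """Cosine similarity between the observed centroid cluster and the
    theoretical averagine envelope of a candidate monoisotopic mass at
    charge ``z`` — the score ``deconvolve`` maximizes."""
    env = _cached_envelope(max(mono, 1.0), envelope_truncation)
    spacing = ISOTOPE_SPACING / z
    mz0 = (mono + z * PROTON_MASS) / z
    tol = min(0.3 * spacing, max(0.004, 15e-6 * mz0))
    score, _, _, _ = _score_candidate(centroids.mz, centroids.intensity,
                                      z, env, mono, tol)
    return score


def deconvolve(s: Spectrum, settings: PickerSettings = PickerSettings(),
               envelope_truncation: float = 0.99995) -> list[DeconvolvedSpecies]:
    """SNAP-style deconvolution of an isotopically resolved spectrum.

    Profile input is centroided first.  Starting from the most intense
    unassigned peak, candidate charges are scanned by isotope-grid coherence,
    an averagine envelope is fit by sliding the monoisotopic assignment, and
    the best (charge, monoisotopic mass) is kept if it passes the quality
    factor, S/N and intensity thresholds.  Species from different charge
    states whose masses agree within 5 ppm are merged by default.
    """
    if len(s) == 0 or float(np.max(s.intensity, initial=0.0)) <= 0:
        return []
    cent = centroid(s) if is_profile(s) else s
    if len(cent) == 0:
        return []
    mz_arr = cent.mz.copy()
    ints = cent.intensity.copy()

    species: list[DeconvolvedSpecies] = []
    guard = 0
    while guard < 2000:
        guard += 1
        seed = int(np.argmax(ints))
        height = ints[seed]
        if height < settings.intensity_threshold:
            break
        noise = _local_noise(Spectrum(mz_arr, np.where(ints > 0, ints, 0.0)),
                             mz_arr[seed])
        snr = height / noise if noise > 0 else 1e6

        best = None  # (score, qf, z, mono, used, abundance)
        for z in range(1, settings.max_charge + 1):
            spacing = ISOTOPE_SPACING / z
            tol = min(0.3 * spacing, max(0.004, 15e-6 * mz_arr[seed]))
            cluster = _collect_cluster(mz_arr, ints, seed, z, tol)
            if len(cluster) < 3 and z > 1:
                continue
            approx_mass = (mz_arr[seed] - PROTON_MASS) * z
            if approx_mass <= 0:
                continue
            env = _cached_envelope(approx_mass, envelope_truncation)
            k_apex = int(np.argmax(env.probabilities))
            apex_neutral = (mz_arr[seed] - PROTON_MASS) * z
            for d in range(max(0, k_apex - 4), min(env.offsets.size, k_apex + 5)):
                mono = apex_neutral - env.offsets[d]
                score, qf, used, obs = _score_candidate(
                    mz_arr, ints, z, env, mono, tol)
                if seed not in used:
                    continue
                cand = (score, qf, z, mono, tuple(used), float(obs.sum()))
                if best is None:
                    best = cand
                elif score > best[0] * 1.01:
                    best = cand
                elif score > best[0] * 0.99 and mono < best[3] - 0.5:
                    # off-by-one-isotope tie: deterministic lower-mass choice
                    best = (score, qf, z, mono, tuple(used), float(obs.sum()),
                            "isotope-tie")
        if best is None:
            ints[seed] = 0.0
            continue
        score, qf, z, mono, used, abundance = best[:6]
        flags = ("isotope-tie",) if len(best) > 6 else ()
        passed = (qf >= settings.quality_factor_threshold and
                  snr >= settings.snr_threshold and
                  height >= settings.intensity_threshold and score > 0)
        if passed:
            species.append(DeconvolvedSpecies(
                monoisotopic_mass=float(mono), charge=int(z),
                abundance=float(abundance), fit_score=min(1.0, score),
                snr=float(snr), quality_factor=float(qf), flags=flags))
        # consume the cluster either way so the loop advances
        for j in used:
            ints[j] = 0.0
        ints[seed] = 0.0

    if settings.merge_charge_states:
        species = _merge_charge_states(species)
    species.sort(key=lambda sp: (-sp.abundance, sp.monoisotopic_mass))
    return species


def _merge_charge_states(species, ppm: float = 5.0):
    merged: list[DeconvolvedSpecies] = []
    for sp in sorted(species, key=lambda x: -x.abundance):
        for m in merged:
            if abs(sp.monoisotopic_mass - m.monoisotopic_mass) <= \
                    ppm * 1e-6 * m.monoisotopic_mass:
                m.abundance += sp.abundance
                m.fit_score = max(m.fit_score, sp.fit_score)
                m.snr = max(m.snr, sp.snr)
                break
        else:
            merged.append(DeconvolvedSpecies(**{
                k: getattr(sp, k) for k in (
                    "monoisotopic_mass", "charge", "abundance", "fit_score",
                    "snr", "quality_factor", "flags")}))
    return merged


def quantify(species: Sequence[DeconvolvedSpecies],
             group_by: Optional[Sequence[str]] = None) -> dict[str, float]:
    """Relative proportions by summed abundance, optionally grouped by label.

    ``group_by`` gives one composition label per species; species sharing a
    label are pooled.  Proportions sum to 1.
    """
    if len(species) == 0:
        raise ConfigurationError("no species to quantify")
    labels = (list(group_by) if group_by is not None
              else [f"species_{i}" for i in range(len(species))])
    if len(labels) != len(species):
        raise ConfigurationError("group_by length mismatch")
    totals: dict[str, float] = {}
    for sp, lab in zip(species, labels):
        totals[lab] = totals.get(lab, 0.0) + sp.abundance
    grand = sum(totals.values())
    if grand <= 0:
        raise DataInconsistencyError("total abundance is zero")
    return {lab: v / grand for lab, v in totals.items()}
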