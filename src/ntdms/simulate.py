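"""Ground-truth generators for native MS1 charge-envelope spectra, CAD
fragment spectra with position-faithful adduct retention, and mobilograms.

Every generator is a pure function of (config, seed): the same seed yields
byte-identical output.  Each artifact comes with a ``SyntheticTruth`` record
sufficient to score any downstream recovery without other inputs.

Defaults mirror the measurement conditions of isotopically resolved native
FTICR spectra of the cardiac troponin system: a discrete-Gaussian charge
envelope (18-21+ centred at 19+ for the 77 kDa heterotrimer, 6-8+ for the
18.4 kDa TnC monomer), Gaussian peak shapes set by resolving power, an
additive baseline plus multiplicative per-peak intensity scatter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .chem import PROTON_MASS, Proteoform, mz_of, neutral_mass, species_mass
from .errors import ConfigurationError
from .fragments import make_ion
from .mobility import GasParameters, Mobilogram, CCSValue, mobility_from_ccs
from .spectra import Spectrum, isotope_envelope

SIGMA_TO_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class GeneratorConfig:
    """Shared knobs for the spectrum generators.

    ``species`` pairs a Proteoform/AssemblySpecies (or a bare mass via
    FixedMassSubunit) with its relative proportion; proportions must be
    non-negative and sum to at most 1.
    """

    species: tuple = ()
    charge_center: float = 19.0
    charge_range: tuple[int, int] = (18, 21)
    charge_sigma: float = 1.0
    resolving_power: float = 150_000.0
    baseline_noise: float = 0.0        # additive Gaussian sigma, counts
    peak_cv: float = 0.0               # multiplicative per-peak scatter
    total_intensity: float = 1e8
    seed: int = 0

    def __post_init__(self):
        props = [p for _, p in self.species]
        if any(p < 0 for p in props):
            raise ConfigurationError("proportions must be >= 0")
        if sum(props) > 1 + 1e-9:
            raise ConfigurationError("proportions sum above 1")
        if self.resolving_power <= 0:
            raise ConfigurationError("resolving power must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated artifact."""

    kind: str
    seed: int
    species: list = field(default_factory=list)
    adduct_positions: list = field(default_factory=list)
    cleaved_bonds: list = field(default_factory=list)
    conformers: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def charge_weights(center: float, zrange: tuple[int, int],
                   sigma: float) -> dict[int, float]:
    """Discrete Gaussian over integer charges, normalized on the support."""
    zs = np.arange(zrange[0], zrange[1] + 1)
    w = np.exp(-0.5 * ((zs - center) / sigma) ** 2)
    w /= w.sum()
    return {int(z): float(wi) for z, wi in zip(zs, w)}


def generate_ms1(c: GeneratorConfig) -> tuple[Spectrum, SyntheticTruth]:
    """Isotopically resolved MS1 spectrum of a proteoform mixture.

    Each species contributes its theoretical averagine-shape isotope
    envelope at every charge of the envelope, as Gaussian peaks whose sigma
    follows the configured resolving power, scaled by proportion and charge
    weight, with seeded noise on top.
    """
    if not c.species:
        raise ConfigurationError("no species configured")
    rng = np.random.default_rng(c.seed)
    zw = charge_weights(c.charge_center, c.charge_range, c.charge_sigma)
    entries = []
    for obj, prop in c.species:
        mass = species_mass(obj) if not isinstance(obj, (int, float)) else float(obj)
        label = obj.describe() if hasattr(obj, "describe") else f"{mass:.2f}"
        env = isotope_envelope(mass, truncation=0.9999)
        entries.append((label, mass, prop, env))

    lo = min(mz_of(m + float(e.offsets[0]), max(zw)) for _, m, _, e in entries) - 3
    hi = max(mz_of(m + float(e.offsets[-1]), min(zw)) for _, m, _, e in entries) + 3
    min_sigma = lo / c.resolving_power / SIGMA_TO_FWHM
    step = max(min_sigma / 4.0, 1e-5)
    grid = np.arange(lo, hi, step)
    intensity = np.zeros_like(grid)

    flags = []
    centers_seen = []
    for label, mass, prop, env in entries:
        for z, w in zw.items():
            amp = c.total_intensity * prop * w
            centers = (mass + env.offsets + z * PROTON_MASS) / z
            sigma = centers / c.resolving_power / SIGMA_TO_FWHM
            heights = amp * env.probabilities
            if c.peak_cv > 0:
                heights = heights * np.clip(
                    1.0 + c.peak_cv * rng.standard_normal(heights.size), 0.05, None)
            for mu, s_, h in zip(centers, sigma, heights):
                sel = slice(np.searchsorted(grid, mu - 6 * s_),
                            np.searchsorted(grid, mu + 6 * s_))
                intensity[sel] += h * np.exp(-0.5 * ((grid[sel] - mu) / s_) ** 2)
            spacing = 1.0 / z
            for lab2, c2 in centers_seen:
                if abs(c2 - centers[0]) < spacing and lab2 != label:
                    flags.append(f"overlap:{label}|{lab2}")
            centers_seen.append((label, centers[0]))
    if c.baseline_noise > 0:
        intensity = np.clip(
            intensity + c.baseline_noise * rng.standard_normal(grid.size), 0.0, None)

    truth = SyntheticTruth(
        kind="ms1", seed=c.seed,
        species=[{"label": lab, "mass": m, "proportion": p}
                 for lab, m, p, _ in entries],
        flags=sorted(set(flags)))
    meta = {"generator": "ms1", "seed": c.seed,
            "resolving_power": c.resolving_power}
    return Spectrum(grid, intensity, meta), truth


def generate_ms2(p: Proteoform, adduct_positions: Sequence[int],
                 efficiency: float, c: GeneratorConfig,
                 adduct_loss_probability: float = 0.0,
                 max_fragment_charge: int = 2) -> tuple[Spectrum, SyntheticTruth]:
    """Centroided CAD MS2 spectrum with position-faithful adduct retention.

    Each backbone bond cleaves independently with probability
    ``efficiency`` (seeded); a cleaved bond emits the b and y ions, each
    carrying exactly the adducts whose true residue position lies within its
    span, minus seeded losses at ``adduct_loss_probability`` per adduct.
    Fragment charges are drawn from 1..max_fragment_charge.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ConfigurationError("efficiency must be in [0, 1]")
    if not 0.0 <= adduct_loss_probability <= 1.0:
        raise ConfigurationError("loss probability must be in [0, 1]")
    lo, hi = p.retained_span
    for pos in adduct_positions:
        if not lo <= pos <= hi:
            raise ConfigurationError(f"adduct position {pos} outside chain")
    rng = np.random.default_rng(c.seed)
    L = len(p.retained_residues)
    positions = sorted(adduct_positions)
    mzs, heights = [], []
    cleaved = []
    for j in range(1, L):
        if rng.random() >= efficiency:
            continue
        cleaved.append(j)
        bond_pos = lo + j - 1      # bond between full-numbering bond_pos, +1
        for series, idx in (("b", j), ("y", L - j)):
            if series == "b":
                n_add = sum(1 for q in positions if q <= bond_pos)
            else:
                n_add = sum(1 for q in positions if q > bond_pos)
            if adduct_loss_probability > 0 and n_add:
                n_add -= int(rng.binomial(n_add, adduct_loss_probability))
            z = int(rng.integers(1, max_fragment_charge + 1))
            ion = make_ion(p, series, idx, n_add, z)
            mzs.append(ion.theoretical_mz)
            heights.append(float(1e4 * rng.lognormal(0.0, 0.3)))
    order = np.argsort(mzs)
    mz_arr = np.asarray(mzs)[order] if mzs else np.array([])
    ht_arr = np.asarray(heights)[order] if mzs else np.array([])
    # collapse exact m/z collisions to keep the axis strictly ascending
    if mz_arr.size:
        keep_mz, keep_ht = [mz_arr[0]], [ht_arr[0]]
        for mzv, htv in zip(mz_arr[1:], ht_arr[1:]):
            if mzv - keep_mz[-1] < 1e-9:
                keep_ht[-1] += htv
            else:
                keep_mz.append(mzv)
                keep_ht.append(htv)
        mz_arr, ht_arr = np.asarray(keep_mz), np.asarray(keep_ht)
    truth = SyntheticTruth(
        kind="ms2", seed=c.seed,
        species=[{"label": p.describe(), "mass": neutral_mass(p)}],
        adduct_positions=list(positions), cleaved_bonds=cleaved)
    meta = {"generator": "ms2", "seed": c.seed, "centroided": True,
            "efficiency": efficiency}
    return Spectrum(mz_arr, ht_arr, meta), truth


def generate_mobilogram(conformers: Sequence[tuple[float, float, float]],
                        charge: int, ion_mass: float,
                        g: GasParameters = GasParameters(),
                        c: Optional[GeneratorConfig] = None,
                        axis: Optional[np.ndarray] = None
                        ) -> tuple[Mobilogram, SyntheticTruth]:
    """Gaussian mobilogram at target CCS values.

    ``conformers`` lists (ccs in A^2, weight, width in A^2 FWHM-equivalent
    of the CCS peak); peaks are placed at the 1/K0 implied by each CCS.
    """
    if not conformers:
        raise ConfigurationError("no conformers")
    if any(w <= 0 for _, _, w in conformers):
        raise ConfigurationError("widths must be positive")
    c = c or GeneratorConfig()
    rng = np.random.default_rng(c.seed)
    centers, sigmas, weights = [], [], []
    for ccs, wt, width in conformers:
        mm = mobility_from_ccs(CCSValue(ccs=ccs, charge=charge, gas=g), ion_mass, g)
        scale = mm.inverse_K0 / ccs          # 1/K0 is linear in CCS
        centers.append(mm.inverse_K0)
        sigmas.append(width * scale / SIGMA_TO_FWHM)
        weights.append(wt)
    wsum = sum(weights)
    weights = [w / wsum for w in weights]
    if axis is None:
        lo = min(c0 - 8 * s0 for c0, s0 in zip(centers, sigmas))
        hi = max(c0 + 8 * s0 for c0, s0 in zip(centers, sigmas))
        axis = np.linspace(lo, hi, 4000)
    intensity = np.zeros_like(axis)
    for c0, s0, w in zip(centers, sigmas, weights):
        intensity += w / (s0 * np.sqrt(2 * np.pi)) * \
            np.exp(-0.5 * ((axis - c0) / s0) ** 2)
    if c.baseline_noise > 0:
        intensity = np.clip(
            intensity + c.baseline_noise * rng.standard_normal(axis.size),
            0.0, None)
    truth = SyntheticTruth(
        kind="mobilogram", seed=c.seed,
        conformers=[{"ccs": ccs, "weight": w, "inverse_K0": c0}
                    for (ccs, _, _), w, c0 in zip(conformers, weights, centers)])
    return Mobilogram(axis, intensity, charge=charge, ion_mass=ion_mass,
                      metadata={"generator": "mobilogram", "seed": c.seed}), truth


def egta_series(base_ccs: float = 4880.0, charge: int = 20,
                ion_mass: float = 77136.0, levels: int = 4, seed: int = 0,
                g: GasParameters = GasParameters()):
    """Emulate a chelator titration: each level adds one more, wider and
    larger-CCS conformer, mimicking progressive complex unfolding."""
    out = []
    for i in range(levels):
        confs = [(base_ccs * (1 + 0.06 * k), 1.0 / (k + 1), 40.0 + 15.0 * k)
                 for k in range(i + 1)]
        cfg = GeneratorConfig(seed=seed + i, baseline_noise=0.0)
        out.append(generate_mobilogram(confs, charge, ion_mass, g, cfg))
    return out
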