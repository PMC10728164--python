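"""Mason-Schamps conversion between reduced mobility and collision cross
section, CCS-vs-charge regression, and mobilogram conformer summaries.

CCS = (3/16) * sqrt(2*pi / (mu * kB * T)) * z * e / (N0 * K0)

with mu the reduced mass of the ion-gas pair, T the drift-region
temperature, N0 the buffer-gas number density at standard conditions
(Loschmidt constant, consistent with the *reduced*-mobility convention) and
K0 the reduced mobility.  Mobilities are handled in the TIMS-native unit
1/K0 (V s / cm^2); CCS values are reported in square angstroms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .errors import ConfigurationError

DA_TO_KG = 1.66053906660e-27


@dataclass(frozen=True)
class GasParameters:
    """Buffer-gas and physical constants; fixed in config, never recomputed."""

    gas_mass: float = 28.0134          # N2, Da
    temperature: float = 305.0         # K, drift region
    N0: float = 2.68678e25             # m^-3, Loschmidt number density
    kb: float = 1.380649e-23           # J/K
    e: float = 1.602176634e-19         # C

    def __post_init__(self):
        if min(self.gas_mass, self.temperature, self.N0, self.kb, self.e) <= 0:
            raise ConfigurationError("gas parameters must all be positive")


@dataclass(frozen=True)
class MobilityMeasurement:
    inverse_K0: float                  # V s / cm^2
    charge: int
    ion_mass: float                    # Da

    def __post_init__(self):
        if self.inverse_K0 <= 0:
            raise ConfigurationError("1/K0 must be positive")
        if self.charge < 1:
            raise ConfigurationError("charge must be >= 1")


@dataclass(frozen=True)
class CCSValue:
    ccs: float                         # A^2
    charge: int
    gas: GasParameters = GasParameters()

    def __post_init__(self):
        if self.ccs <= 0:
            raise ConfigurationError("CCS must be positive")


@dataclass
class Mobilogram:
    inverse_K0: np.ndarray
    intensity: np.ndarray
    charge: int
    ion_mass: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inverse_K0 = np.asarray(self.inverse_K0, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.inverse_K0.shape != self.intensity.shape:
            raise ConfigurationError("axis/intensity length mismatch")
        if np.any(np.diff(self.inverse_K0) <= 0):
            raise ConfigurationError("1/K0 axis must be ascending")
        if np.any(self.intensity < 0):
            raise ConfigurationError("negative intensities")


@dataclass
class Conformer:
    apex_inverse_K0: float
    apex_ccs: float
    fwhm_inverse_K0: float
    share: float


def _prefactor(ion_mass: float, charge: int, g: GasParameters) -> float:
    """(3/16) sqrt(2 pi / (mu kB T)) z e / N0 — everything except mobility,
    in SI units."""
    m = ion_mass * DA_TO_KG
    M = g.gas_mass * DA_TO_KG
    mu = m * M / (m + M)
    return (3.0 / 16.0) * math.sqrt(2.0 * math.pi / (mu * g.kb * g.temperature)) \
        * charge * g.e / g.N0


def ccs_from_mobility(m: MobilityMeasurement,
                      g: GasParameters = GasParameters()) -> CCSValue:
    """Mason-Schamps forward conversion; returns CCS in A^2."""
    K0_si = (1.0 / m.inverse_K0) * 1e-4          # cm^2/(V s) -> m^2/(V s)
    ccs_m2 = _prefactor(m.ion_mass, m.charge, g) / K0_si
    return CCSValue(ccs=ccs_m2 * 1e20, charge=m.charge, gas=g)


def mobility_from_ccs(c: CCSValue, ion_mass: float,
                      g: Optional[GasParameters] = None) -> MobilityMeasurement:
    """Exact algebraic inverse of the forward conversion."""
    g = g or c.gas
    if c.ccs <= 0:
        raise ConfigurationError("CCS must be positive")
    K0_si = _prefactor(ion_mass, c.charge, g) / (c.ccs * 1e-20)
    inverse_K0 = 1.0 / (K0_si * 1e4)
    return MobilityMeasurement(inverse_K0=inverse_K0, charge=c.charge,
                               ion_mass=ion_mass)


def ccs_charge_fit(points: Sequence[tuple[int, float]]):
    """OLS fit of CCS against charge state: returns (slope, intercept, r2).

    Native proteins show a near-linear CCS/charge relationship; the fit
    summarizes one molecular form measured at several charges.
    """
    if len(points) < 2:
        raise ConfigurationError("need at least 2 points")
    z = np.array([p[0] for p in points], dtype=float)
    ccs = np.array([p[1] for p in points], dtype=float)
    if np.all(z == z[0]):
        raise ConfigurationError("all charges identical; fit undefined")
    res = stats.linregress(z, ccs)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def summarize_mobilogram(m: Mobilogram, min_prominence: float = 0.05,
                         g: GasParameters = GasParameters()) -> list[Conformer]:
    """Detect conformer peaks in a mobilogram and summarize each.

    ``min_prominence`` is relative to the maximum intensity.  Apex 1/K0 is
    refined by 3-point parabolic interpolation; each conformer's share is
    its integrated area between the midpoints to neighbouring apexes,
    normalized so shares sum to 1.
    """
    y = m.intensity
    ymax = float(np.max(y, initial=0.0))
    if ymax <= 0 or np.allclose(y, y[0]):
        return []
    peaks, props = signal.find_peaks(y, prominence=min_prominence * ymax)
    if peaks.size == 0:
        return []
    widths, _, _, _ = signal.peak_widths(y, peaks, rel_height=0.5)
    dx = float(np.median(np.diff(m.inverse_K0)))
    apexes = []
    for p in peaks:
        x = m.inverse_K0
        if 0 < p < y.size - 1:
            denom = y[p - 1] - 2 * y[p] + y[p + 1]
            d = 0.5 * (y[p - 1] - y[p + 1]) / denom if denom < 0 else 0.0
            d = float(np.clip(d, -0.5, 0.5))
            apexes.append(x[p] + d * dx)
        else:
            apexes.append(float(x[p]))
    # partition the axis at midpoints between adjacent apexes for area shares
    bounds = [m.inverse_K0[0]]
    for a, b in zip(apexes, apexes[1:]):
        bounds.append(0.5 * (a + b))
    bounds.append(m.inverse_K0[-1])
    areas = []
    for lo, hi in zip(bounds, bounds[1:]):
        sel = (m.inverse_K0 >= lo) & (m.inverse_K0 <= hi)
        areas.append(float(np.trapezoid(y[sel], m.inverse_K0[sel])) if sel.sum() > 1
                     else 0.0)
    total = sum(areas)
    out = []
    for apex, w, area in zip(apexes, widths, areas):
        ccs = ccs_from_mobility(
            MobilityMeasurement(inverse_K0=apex, charge=m.charge,
                                ion_mass=m.ion_mass), g).ccs
        out.append(Conformer(apex_inverse_K0=float(apex), apex_ccs=float(ccs),
                             fwhm_inverse_K0=float(w * dx),
                             share=area / total if total > 0 else 0.0))
    return out
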