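"""Experimental reference targets and the derivations that produce them.

The optimization targets five properties of liquid water at 1 bar: the
density isobar (260–360 K), the static dielectric constant, the
self-diffusion coefficient, and the position and height of the first
oxygen-oxygen RDF peak.  Two of the targets are not raw experimental
numbers but derived quantities:

* the dielectric target is the *nuclear* contribution
  ``ε_N = ε_r / ε_e`` (with ``ε_e ≈ n² = 1.78``), the value a
  charge-scaling-compatible nonpolarizable model should reproduce;
* the diffusion target is the experimental value reduced by the
  Yeh-Hummer periodic-boundary correction ``ξ k_B T / (6 π η L)`` so it
  matches what a finite periodic box should yield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import yaml

from .units import BOLTZMANN_J_PER_K

__all__ = [
    "PropertyTarget",
    "ReferenceSet",
    "RdfCurve",
    "ecc_dielectric_target",
    "finite_size_diffusion_target",
    "rdf_first_peak",
    "XI_CUBIC",
    "EPS_ELECTRONIC",
    "TEMPERATURE_GRID_K",
]

#: Self-interaction constant of a point particle on a cubic lattice
#: (the Yeh-Hummer correction's geometry factor for a cubic box).
XI_CUBIC = 2.837297

#: Electronic (high-frequency) dielectric constant of water, ≈ n².
EPS_ELECTRONIC = 1.78

#: Temperatures (K) of the density-isobar grid at 1 bar.
TEMPERATURE_GRID_K = (260.0, 280.0, 300.0, 320.0, 340.0, 360.0)

# Literature values for the density of liquid water at 1 bar (kg/m^3) on
# the grid above; 260 K is the supercooled branch.  These are standard
# handbook/equation-of-state values shipped as a convenience default —
# users fitting against a specific tabulation should override them.
_LITERATURE_DENSITY_1BAR: Dict[float, float] = {
    260.0: 997.1,
    280.0: 999.9,
    300.0: 996.5,
    320.0: 989.4,
    340.0: 979.5,
    360.0: 967.4,
}

Value = Union[float, Dict[float, float]]


@dataclass(frozen=True)
class PropertyTarget:
    """One named reference property with units and provenance note."""

    name: str
    value: Value
    units: str
    source: str = ""

    def __post_init__(self) -> None:
        values = self.value.values() if isinstance(self.value, dict) else (self.value,)
        if not all(math.isfinite(v) for v in values):
            raise ValueError(f"target {self.name!r} has non-finite value(s)")

    def values_array(self) -> np.ndarray:
        if isinstance(self.value, dict):
            return np.array([self.value[k] for k in sorted(self.value)], dtype=float)
        return np.array([self.value], dtype=float)


@dataclass
class ReferenceSet:
    """The collection of property targets driving the cost function."""

    targets: Dict[str, PropertyTarget] = field(default_factory=dict)
    eps_e: float = EPS_ELECTRONIC
    temperature_grid: Tuple[float, ...] = TEMPERATURE_GRID_K

    def __getitem__(self, name: str) -> PropertyTarget:
        return self.targets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.targets

    @classmethod
    def default(cls) -> "ReferenceSet":
        """The standard target set for ambient-pressure water.

        eps_r is the ECC-reduced (nuclear) dielectric target 44.5; D_OW is
        already corrected for the finite size of an 832-molecule box.
        """
        targets = {
            "rho_1bar": PropertyTarget(
                "rho_1bar", dict(_LITERATURE_DENSITY_1BAR), "kg/m^3",
                "literature density isobar, 260-360 K",
            ),
            "eps_r": PropertyTarget(
                "eps_r", 44.5, "-", "nuclear dielectric target eps_r/eps_e"),
            "D_OW": PropertyTarget(
                "D_OW", 2.16e-5, "cm^2/s",
                "self-diffusion at 300 K, Yeh-Hummer corrected for 832 waters"),
            "rdf_1p": PropertyTarget(
                "rdf_1p", 0.280, "nm", "first O-O RDF peak position"),
            "rdf_1h": PropertyTarget(
                "rdf_1h", 2.58, "-", "first O-O RDF peak height"),
        }
        return cls(targets=targets)

    # --- YAML round trip ---

    def to_dict(self) -> dict:
        return {
            "eps_e": self.eps_e,
            "temperature_grid_K": list(self.temperature_grid),
            "targets": [
                {
                    "name": t.name,
                    "value": ({float(k): float(v) for k, v in t.value.items()}
                              if isinstance(t.value, dict) else float(t.value)),
                    "units": t.units,
                    "source": t.source,
                }
                for t in self.targets.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReferenceSet":
        targets = {
            entry["name"]: PropertyTarget(
                name=entry["name"],
                value=(entry["value"] if not isinstance(entry["value"], dict)
                       else {float(k): float(v) for k, v in entry["value"].items()}),
                units=entry.get("units", ""),
                source=entry.get("source", ""),
            )
            for entry in data["targets"]
        }
        return cls(
            targets=targets,
            eps_e=float(data.get("eps_e", EPS_ELECTRONIC)),
            temperature_grid=tuple(data.get("temperature_grid_K", TEMPERATURE_GRID_K)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def ecc_dielectric_target(eps_r_exp: float, eps_e: float = EPS_ELECTRONIC) -> float:
    """Nuclear dielectric constant ``ε_N = ε_r / ε_e``.

    This is the dielectric constant a nonpolarizable, charge-scaling
    compatible water model should exhibit: the experimental static value
    stripped of the electronic (instantaneous) response.
    """
    if eps_e <= 0:
        raise ValueError(f"eps_e must be positive, got {eps_e}")
    if eps_e < 1.0:
        raise ValueError(f"eps_e must be >= 1 for a dielectric, got {eps_e}")
    if eps_r_exp < eps_e:
        raise ValueError(f"total eps_r ({eps_r_exp}) cannot be below eps_e ({eps_e})")
    return eps_r_exp / eps_e


def finite_size_diffusion_target(D_exp: float, T: float, eta: float, L: float) -> float:
    """Finite-box self-diffusion target in cm²/s (Yeh-Hummer correction).

    A periodic cubic box of edge ``L`` suppresses self-diffusion by
    ``ΔD = ξ k_B T / (6 π η L)`` relative to the infinite system, so the
    value an N-molecule simulation should match is ``D_exp - ΔD``.

    Parameters
    ----------
    D_exp : float
        Experimental (infinite-system) self-diffusion coefficient, cm²/s.
    T : float
        Temperature, K.
    eta : float
        Shear viscosity, Pa·s.
    L : float
        Cubic box edge, nm.
    """
    if D_exp <= 0 or T <= 0 or eta <= 0:
        raise ValueError("D_exp, T and eta must all be positive")
    if L <= 0:
        raise ValueError(f"box edge L must be positive, got {L}")
    delta_m2_per_s = XI_CUBIC * BOLTZMANN_J_PER_K * T / (6.0 * math.pi * eta * L * 1e-9)
    return D_exp - delta_m2_per_s * 1e4  # m^2/s -> cm^2/s


@dataclass(frozen=True)
class RdfCurve:
    """A radial distribution function g(r) sampled on an increasing grid."""

    r: np.ndarray  # nm
    g: np.ndarray  # dimensionless

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if r.shape != g.shape or r.ndim != 1:
            raise ValueError("r and g must be 1-D arrays of equal length")
        if np.any(np.diff(r) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("g(r) must be non-negative")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)

    @classmethod
    def from_file(cls, path) -> "RdfCurve":
        data = np.loadtxt(path)
        return cls(r=data[:, 0], g=data[:, 1])

    def to_file(self, path) -> None:
        np.savetxt(path, np.column_stack([self.r, self.g]), fmt="%.6f")


def rdf_first_peak(curve: RdfCurve) -> Tuple[float, float]:
    """Position (nm) and height of the *first* local maximum of g(r) above 1.

    The discrete maximum is refined by fitting a parabola through the three
    points around it, giving sub-grid accuracy for smooth peaks.  "First"
    means smallest r, even when a later peak is higher.
    """
    r, g = curve.r, curve.g
    if len(r) < 3:
        raise ValueError("need at least 3 points to locate a peak")
    interior = np.flatnonzero(
        (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:]) & (g[1:-1] > 1.0)
    )
    if interior.size == 0:
        raise ValueError("no local maximum above g = 1 found")
    i = int(interior[0]) + 1
    # parabola through (r[i-1], g[i-1]), (r[i], g[i]), (r[i+1], g[i+1])
    coeffs = np.polyfit(r[i - 1:i + 2], g[i - 1:i + 2], 2)
    if coeffs[0] >= 0:  # degenerate (flat/colinear): keep grid point
        return float(r[i]), float(g[i])
    pos = -coeffs[1] / (2.0 * coeffs[0])
    height = float(np.polyval(coeffs, pos))
    return float(pos), height
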