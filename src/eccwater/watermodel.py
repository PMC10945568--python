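"""Four-site rigid water models: parameters, geometry, and electrostatic moments.

A four-site (TIP4P-family) water model is fully defined by six scalars:
Lennard-Jones ``sigma`` and ``epsilon`` on the oxygen, the hydrogen partial
charge ``q_H`` (the massless M site carries ``q_M = -2 q_H`` so the molecule
is neutral by construction), the O-H bond length ``d_OH``, the O-M distance
``d_OM``, and the H-O-H angle ``theta``.  The M site sits on the H-O-H
bisector, displaced from the oxygen toward the hydrogens.

Geometries are built in a canonical molecular frame — oxygen at the origin,
the bisector along +z, hydrogens in the xz-plane — so that the molecular
dipole ``mu`` and the tetrahedral quadrupole ``Q_T`` are reproducible
bit-for-bit.  ``Q_T`` is the in-plane anisotropy ``(Q_xx - Q_yy)/2`` of the
traceless quadrupole tensor about the oxygen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import yaml

from .units import E_NM_TO_DEBYE, E_NM2_TO_DEBYE_ANGSTROM

__all__ = [
    "WaterModelParams",
    "ParameterBounds",
    "SiteGeometry",
    "MolecularMoments",
    "DEFAULT_BOUNDS",
    "INITIAL_GUESS",
    "PRESETS",
    "build_geometry",
    "dipole_moment",
    "quadrupole_qt",
    "molecular_moments",
    "scale_charge",
    "normalize_params",
    "denormalize_params",
]

PARAM_NAMES = ("sigma", "epsilon", "q_H", "d_OH", "d_OM", "theta")


@dataclass(frozen=True)
class WaterModelParams:
    """The six free parameters of a four-site rigid water model.

    Parameters
    ----------
    sigma : float
        Lennard-Jones diameter on the oxygen, nm.
    epsilon : float
        Lennard-Jones well depth on the oxygen, kJ/mol.
    q_H : float
        Partial charge on each hydrogen, e.  The M-site charge is the
        implied ``-2 q_H`` and is never stored independently.
    d_OH : float
        O-H bond length, nm.
    d_OM : float
        O-M (oxygen to massless charge site) distance, nm.
    theta : float
        H-O-H angle, degrees.
    """

    sigma: float
    epsilon: float
    q_H: float
    d_OH: float
    d_OM: float
    theta: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")

    @property
    def q_M(self) -> float:
        """Charge on the M site, e (structural neutrality: ``-2 q_H``)."""
        return -2.0 * self.q_H

    def as_array(self) -> np.ndarray:
        """The six parameters as a vector in canonical order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "WaterModelParams":
        vals = list(values)
        if len(vals) != 6:
            raise ValueError(f"expected 6 parameters, got {len(vals)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, vals))))

    def replace(self, **changes: float) -> "WaterModelParams":
        return replace(self, **changes)

    # --- YAML parameter-file interface (sigma_nm, epsilon_kjmol, ...) ---

    _YAML_KEYS = {
        "sigma": "sigma_nm",
        "epsilon": "epsilon_kjmol",
        "q_H": "q_H_e",
        "d_OH": "d_OH_nm",
        "d_OM": "d_OM_nm",
        "theta": "theta_deg",
    }

    def to_dict(self) -> Dict[str, float]:
        return {key: float(getattr(self, name)) for name, key in self._YAML_KEYS.items()}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "WaterModelParams":
        missing = [key for key in cls._YAML_KEYS.values() if key not in data]
        if missing:
            raise ValueError(f"parameter file is missing keys: {missing}")
        return cls(**{name: float(data[key]) for name, key in cls._YAML_KEYS.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WaterModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (lower, upper) box constraints, same units as the params."""

    sigma: Tuple[float, float]
    epsilon: Tuple[float, float]
    q_H: Tuple[float, float]
    d_OH: Tuple[float, float]
    d_OM: Tuple[float, float]
    theta: Tuple[float, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must satisfy lower < upper, got ({lo}, {hi})")

    def lower_array(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in PARAM_NAMES], dtype=float)

    def upper_array(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in PARAM_NAMES], dtype=float)

    def contains(self, params: WaterModelParams, atol: float = 0.0) -> bool:
        x = params.as_array()
        return bool(np.all(x >= self.lower_array() - atol) and np.all(x <= self.upper_array() + atol))

    def violations(self, params: WaterModelParams) -> Dict[str, float]:
        """Names of out-of-bounds parameters mapped to their values."""
        out: Dict[str, float] = {}
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            value = getattr(params, name)
            if not (lo <= value <= hi):
                out[name] = value
        return out


#: Search-box boundaries used when optimizing the six parameters.
DEFAULT_BOUNDS = ParameterBounds(
    sigma=(0.3050, 0.3250),
    epsilon=(0.5000, 1.0000),
    q_H=(0.3500, 0.7000),
    d_OH=(0.0900, 0.1000),
    d_OM=(0.0120, 0.0180),
    theta=(100.00, 110.00),
)

#: Seeding point for the optimization (center-ish of the search box).
INITIAL_GUESS = WaterModelParams(
    sigma=0.3150, epsilon=0.7500, q_H=0.5500, d_OH=0.0960, d_OM=0.0150, theta=105.00
)

#: Published four-site models, keyed by preset name.
PRESETS: Dict[str, WaterModelParams] = {
    "eccw2024": WaterModelParams(
        sigma=0.315480, epsilon=0.761154, q_H=0.605689,
        d_OH=0.092084, d_OM=0.016388, theta=108.7392,
    ),
    "tip4p2005": WaterModelParams(
        sigma=0.31589, epsilon=0.7749, q_H=0.5564,
        d_OH=0.09572, d_OM=0.01546, theta=104.52,
    ),
    "tip4pfb": WaterModelParams(
        sigma=0.31655, epsilon=0.74928, q_H=0.52587,
        d_OH=0.09572, d_OM=0.010527, theta=104.52,
    ),
    "opc4": WaterModelParams(
        sigma=0.316655, epsilon=0.89036, q_H=0.6791,
        d_OH=0.08724, d_OM=0.01594, theta=103.60,
    ),
}

CANONICAL_FRAME = "O-origin, bisector +z, H in xz-plane"


@dataclass(frozen=True)
class SiteGeometry:
    """Explicit charged-site coordinates of one rigid water molecule.

    Sites are ordered (O, H1, H2, M); positions in nm in the canonical
    frame; charges in e.  Charge neutrality is exact by construction.
    """

    labels: Tuple[str, ...]
    positions: np.ndarray  # (4, 3) nm
    charges: np.ndarray    # (4,) e
    frame: str = CANONICAL_FRAME

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        chg = np.asarray(self.charges, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(f"positions must be ({len(self.labels)}, 3), got {pos.shape}")
        if chg.shape != (len(self.labels),):
            raise ValueError(f"charges must be ({len(self.labels)},), got {chg.shape}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", chg)

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SiteGeometry":
        """Rigidly transformed copy (positions -> R @ r + t); charges unchanged."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SiteGeometry(
            labels=self.labels,
            positions=self.positions @ R.T + t,
            charges=self.charges.copy(),
            frame="transformed",
        )


@dataclass(frozen=True)
class MolecularMoments:
    """Dipole magnitude (D) and tetrahedral quadrupole Q_T (D Å)."""

    mu: float
    q_t: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.q_t)):
            raise ValueError("moments must be finite")
        if self.mu < 0:
            raise ValueError("dipole magnitude must be non-negative")


def build_geometry(params: WaterModelParams) -> SiteGeometry:
    """Place the four sites of ``params`` in the canonical molecular frame.

    Oxygen at the origin; the H-O-H bisector along +z; both hydrogens in
    the xz-plane at distance ``d_OH`` from O with opening angle ``theta``;
    the M site on the bisector at ``d_OM`` from O, on the hydrogen side:

    - H1,2 at ``(±d_OH sin(θ/2), 0, d_OH cos(θ/2))``
    - M at ``(0, 0, d_OM)``
    """
    half = math.radians(params.theta) / 2.0
    sin_h, cos_h = math.sin(half), math.cos(half)
    positions = np.array(
        [
            [0.0, 0.0, 0.0],
            [params.d_OH * sin_h, 0.0, params.d_OH * cos_h],
            [-params.d_OH * sin_h, 0.0, params.d_OH * cos_h],
            [0.0, 0.0, params.d_OM],
        ]
    )
    charges = np.array([0.0, params.q_H, params.q_H, -2.0 * params.q_H])
    return SiteGeometry(labels=("O", "H1", "H2", "M"), positions=positions, charges=charges)


def dipole_moment(geom: SiteGeometry) -> float:
    """Dipole magnitude ``|Σ_i q_i r_i|`` of a neutral site set, in debye.

    Raises if the geometry carries a net charge — the dipole of a charged
    system depends on the choice of origin and is not a model property.
    """
    if abs(geom.total_charge) > 1e-12:
        raise ValueError(
            f"geometry has net charge {geom.total_charge:g} e; dipole would be origin-dependent"
        )
    vec = geom.charges @ geom.positions  # e nm
    return float(np.linalg.norm(vec)) * E_NM_TO_DEBYE


def quadrupole_qt(geom: SiteGeometry) -> float:
    """Tetrahedral quadrupole ``Q_T = (Q_xx - Q_yy)/2`` in debye-angstrom.

    Evaluates the full traceless quadrupole tensor about the origin,
    ``Q_ab = 1/2 Σ_i q_i (3 r_a r_b - r² δ_ab)``, and returns its in-plane
    anisotropy.  Requires the canonical frame (hydrogens in the xz-plane)
    for the value to carry the conventional water-model meaning.
    """
    if geom.frame != CANONICAL_FRAME:
        raise ValueError("Q_T is defined in the canonical frame (bisector +z, H in xz-plane)")
    r = geom.positions
    q = geom.charges
    r2 = np.sum(r * r, axis=1)
    Q = 0.5 * np.einsum("i,iab->ab", q, 3.0 * r[:, :, None] * r[:, None, :]) \
        - 0.5 * np.diag([np.dot(q, r2)] * 3)
    return float((Q[0, 0] - Q[1, 1]) / 2.0) * E_NM2_TO_DEBYE_ANGSTROM


def molecular_moments(params: WaterModelParams) -> MolecularMoments:
    """Convenience: both moments straight from the six parameters."""
    geom = build_geometry(params)
    return MolecularMoments(mu=dipole_moment(geom), q_t=quadrupole_qt(geom))


def scale_charge(q: float, eps_e: float) -> float:
    """Electronic-continuum (ECC) charge scaling: ``q / sqrt(eps_e)``.

    ``eps_e`` is the electronic (high-frequency) part of the dielectric
    constant of the medium, ≈ n² = 1.78 for water.  Values below 1 are
    unphysical for a dielectric and rejected.
    """
    if eps_e < 1.0:
        raise ValueError(f"eps_e must be >= 1, got {eps_e}")
    return q / math.sqrt(eps_e)


def _check_in_bounds(params: WaterModelParams, bounds: ParameterBounds, strict: bool) -> None:
    bad = bounds.violations(params)
    if not bad:
        return
    msg = f"parameters outside bounds: {bad}"
    if strict:
        raise ValueError(msg)
    warnings.warn(msg, stacklevel=3)


def normalize_params(
    params: WaterModelParams, bounds: ParameterBounds = DEFAULT_BOUNDS, strict: bool = True
) -> np.ndarray:
    """Map the six parameters onto the unit cube: ``(x - lo) / (hi - lo)``.

    With ``strict=True`` (the optimizer path) out-of-bounds parameters are
    an error; with ``strict=False`` they only warn, so published models
    lying outside the search box remain computable.
    """
    _check_in_bounds(params, bounds, strict)
    lo, hi = bounds.lower_array(), bounds.upper_array()
    return (params.as_array() - lo) / (hi - lo)


def denormalize_params(x: np.ndarray, bounds: ParameterBounds = DEFAULT_BOUNDS) -> WaterModelParams:
    """Inverse of :func:`normalize_params` for a unit-cube 6-vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise ValueError(f"expected a 6-vector, got shape {x.shape}")
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError(f"normalized components outside [0, 1]: {x}")
    lo, hi = bounds.lower_array(), bounds.upper_array()
    return WaterModelParams.from_array(lo + np.clip(x, 0.0, 1.0) * (hi - lo))
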