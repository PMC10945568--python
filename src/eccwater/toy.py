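"""Synthetic stand-in for the MD property evaluator.

Evaluating a candidate water model for real means running a 20 ns NpT
simulation — far too expensive for testing the optimization machinery.
The toy evaluator replaces that stage with a smooth, instantaneous
parameters → properties map with a *planted optimum*: every target
property equals its reference value multiplied by
``1 + s_p · Σ_j c_j (x_j - x*_j)²`` in normalized coordinates (plus
optional Gaussian noise).  At the planted optimum with zero noise every
property matches its reference exactly and the cost is 0, so optimizer
correctness can be checked against a known answer.

A coupled variant rotates the displacement vector by a fixed orthogonal
matrix before the quadratic form, removing coordinate separability to
stress the search beyond axis-aligned landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .reference_data import RdfCurve, ReferenceSet
from .cost import PropertyResult
from .watermodel import (
    DEFAULT_BOUNDS,
    PRESETS,
    ParameterBounds,
    WaterModelParams,
    normalize_params,
)

__all__ = ["ToyLandscapeConfig", "ToyEvaluator", "evaluate_toy", "generate_rdf_fixture"]


def _random_rotation(dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


@dataclass
class ToyLandscapeConfig:
    """Shape of the planted-optimum landscape.

    ``curvature`` is the per-parameter coefficient vector ``c_j`` of the
    quadratic bowl (normalized coordinates); ``property_scales`` lets
    individual properties respond more or less strongly; ``coupled``
    mixes the parameters through a fixed rotation.  ``noise`` is the
    standard deviation of multiplicative Gaussian noise on each property.
    """

    optimum: WaterModelParams = field(default_factory=lambda: PRESETS["eccw2024"])
    bounds: ParameterBounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    curvature: np.ndarray = field(default_factory=lambda: np.ones(6))
    property_scales: Optional[Dict[str, float]] = None
    noise: float = 0.0
    coupled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.curvature = np.asarray(self.curvature, dtype=float)
        if self.curvature.shape != (6,) or np.any(self.curvature <= 0):
            raise ValueError("curvature must be 6 strictly positive coefficients")
        if self.noise < 0:
            raise ValueError("noise amplitude must be >= 0")
        if not self.bounds.contains(self.optimum):
            raise ValueError("planted optimum must lie within the bounds")
        self.x_opt = normalize_params(self.optimum, self.bounds)
        self.rotation = _random_rotation(6, self.seed) if self.coupled else np.eye(6)

    def deviation(self, x_norm: np.ndarray) -> float:
        """The relative property deviation ``Σ_j c_j ((R Δ)_j)²`` at ``x_norm``."""
        delta = self.rotation @ (np.asarray(x_norm, dtype=float) - self.x_opt)
        return float(np.dot(self.curvature, delta * delta))


class ToyEvaluator:
    """Callable evaluator: ``WaterModelParams -> {name: PropertyResult}``.

    Conforms to the optimizer's evaluator contract; the warm-start hook
    (previous configuration seeding the next run) is accepted and ignored
    since there is no simulation state to hand over.
    """

    def __init__(
        self,
        config: Optional[ToyLandscapeConfig] = None,
        reference: Optional[ReferenceSet] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        self.config = config if config is not None else ToyLandscapeConfig()
        self.reference = reference if reference is not None else ReferenceSet.default()
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        self.n_calls = 0

    def __call__(self, params: WaterModelParams, warm_start=None) -> Dict[str, PropertyResult]:
        cfg = self.config
        if not cfg.bounds.contains(params):
            raise ValueError(f"parameters out of bounds: {cfg.bounds.violations(params)}")
        x = normalize_params(params, cfg.bounds)
        dev = cfg.deviation(x)
        scales = cfg.property_scales or {}
        results: Dict[str, PropertyResult] = {}
        for name, target in self.reference.targets.items():
            factor = 1.0 + scales.get(name, 1.0) * dev
            if cfg.noise > 0:
                factor *= 1.0 + cfg.noise * self.rng.standard_normal()
            values = target.values_array() * factor
            results[name] = PropertyResult(
                name=name, value=(float(values[0]) if values.size == 1 else values.tolist())
            )
        self.n_calls += 1
        return results


def evaluate_toy(
    params: WaterModelParams,
    config: Optional[ToyLandscapeConfig] = None,
    rng: Optional[np.random.Generator] = None,
    reference: Optional[ReferenceSet] = None,
) -> Dict[str, PropertyResult]:
    """One-shot functional form of :class:`ToyEvaluator`."""
    return ToyEvaluator(config=config, reference=reference, rng=rng)(params)


def generate_rdf_fixture(
    peak_position: float,
    peak_height: float,
    spacing: float = 0.002,
    r_max: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    noise: float = 0.0,
) -> RdfCurve:
    """Synthetic O-O RDF with a controlled first peak.

    Zero inside an excluded-volume core, a Gaussian first peak at
    ``peak_position`` reaching ``peak_height``, then damped oscillations
    decaying to the ideal-gas limit g = 1.
    """
    if peak_position <= 0:
        raise ValueError("peak position must be positive")
    if peak_height <= 1:
        raise ValueError("a first peak must rise above g = 1")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    r = np.arange(spacing, r_max + spacing / 2, spacing)
    width = 0.022  # nm, realistic first-shell width
    core = 1.0 / (1.0 + np.exp(-(r - 0.88 * peak_position) / 0.004))
    peak = (peak_height - 1.0) * np.exp(-((r - peak_position) ** 2) / (2 * width**2))
    # damped shell oscillation: zero at the peak, first minimum below 1,
    # weak second maximum near peak + shell spacing
    wavelength = 0.24  # nm, shell spacing of the damped tail
    delta = r - peak_position
    tail = -0.35 * np.exp(-delta / 0.18) * np.sin(2 * np.pi * delta / wavelength)
    # window the oscillation off near the peak so it does not shift the maximum
    tail *= 1.0 - np.exp(-((delta / 0.04) ** 2))
    tail[delta < 0] = 0.0
    g = core * (1.0 + peak + tail)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        g = np.clip(g + noise * rng.standard_normal(g.shape), 0.0, None)
    return RdfCurve(r=r, g=np.clip(g, 0.0, None))
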