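"""Weighted-MAPE cost function comparing simulated properties with targets.

Each property contributes a loss ``f_i = MAPE_i(%) / 10`` — the mean
absolute percentage error rescaled so that a uniform 10% error across the
board gives a cost of exactly 1 — and the total cost is the weighted
average ``C = Σ w_i f_i`` with the weights renormalized to sum to 1 over
the included properties.

Two variants exist:

* ``C_ECC`` includes the dielectric constant (against the ECC-reduced
  target ε_N ≈ 44.5) — the objective actually optimized;
* ``C_G`` ("general") excludes the dielectric constant, making models with
  very different ε comparable on the remaining observables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .reference_data import ReferenceSet

__all__ = [
    "PropertyResult",
    "CostWeights",
    "CostValue",
    "DEFAULT_WEIGHTS",
    "VARIANT_ECC",
    "VARIANT_GENERAL",
    "mape",
    "renormalize_weights",
    "cost",
    "is_better",
]

VARIANT_ECC = "C_ECC"
VARIANT_GENERAL = "C_G"

#: Property excluded by the general variant.
_GENERAL_EXCLUDES = ("eps_r",)

#: Loss rescaling: a property's loss is its MAPE in percent divided by 10.
LOSS_SCALE_PERCENT = 10.0


@dataclass(frozen=True)
class PropertyResult:
    """A simulated property value (or a precomputed MAPE against its target).

    Exactly one of ``value`` / ``mape_percent`` must be supplied; units of
    ``value`` must match the corresponding target.
    """

    name: str
    value: Optional[Union[float, Sequence[float]]] = None
    mape_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.mape_percent is None):
            raise ValueError(f"result {self.name!r}: provide exactly one of value / mape_percent")
        if self.mape_percent is not None and (
            not math.isfinite(self.mape_percent) or self.mape_percent < 0
        ):
            raise ValueError(f"result {self.name!r}: MAPE must be finite and >= 0")

    def values_array(self) -> np.ndarray:
        if self.value is None:
            raise ValueError(f"result {self.name!r} carries only a precomputed MAPE")
        return np.atleast_1d(np.asarray(self.value, dtype=float))


def mape(simulated, reference) -> float:
    """Mean absolute percentage error, ``100 · mean(|sim - ref| / |ref|)``."""
    sim = np.atleast_1d(np.asarray(simulated, dtype=float))
    ref = np.atleast_1d(np.asarray(reference, dtype=float))
    if sim.shape != ref.shape:
        raise ValueError(f"shape mismatch: {sim.shape} vs {ref.shape}")
    if np.any(ref == 0):
        raise ValueError("reference contains zeros; percentage error undefined")
    return float(100.0 * np.mean(np.abs(sim - ref) / np.abs(ref)))


@dataclass(frozen=True)
class CostWeights:
    """Per-property weights with inclusion flags."""

    weights: Dict[str, float]
    included: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be strictly positive")
        included = self.included if self.included is not None else frozenset(self.weights)
        unknown = set(included) - set(self.weights)
        if unknown:
            raise ValueError(f"included names without weights: {sorted(unknown)}")
        object.__setattr__(self, "included", frozenset(included))

    def normalized(self) -> Dict[str, float]:
        """Included weights divided by their sum (Σ = 1)."""
        total = sum(self.weights[n] for n in self.included)
        return {n: self.weights[n] / total for n in sorted(self.included)}


#: The standard weights: density dominates, dielectric and diffusion next,
#: the two RDF-peak descriptors share the remainder.  Normalized to 1.
DEFAULT_WEIGHTS = CostWeights(
    weights={
        "rho_1bar": 0.667,
        "eps_r": 0.111,
        "D_OW": 0.111,
        "rdf_1p": 0.0555,
        "rdf_1h": 0.0555,
    }
)


def renormalize_weights(weights: CostWeights, excluded: Iterable[str] = ()) -> CostWeights:
    """Drop ``excluded`` properties and renormalize the rest to sum to 1."""
    excluded = set(excluded)
    keep = weights.included - excluded
    if not keep:
        raise ValueError("cannot exclude every property")
    total = sum(weights.weights[n] for n in keep)
    return CostWeights(
        weights={n: weights.weights[n] / total for n in keep},
        included=frozenset(keep),
    )


@dataclass(frozen=True)
class CostValue:
    """A scalar cost with its variant tag and per-property breakdown."""

    total: float
    variant: str
    breakdown: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total < 0 or not math.isfinite(self.total):
            raise ValueError(f"cost must be finite and >= 0, got {self.total}")

    def __float__(self) -> float:
        return self.total


def cost(
    results: Mapping[str, PropertyResult],
    targets: ReferenceSet,
    weights: CostWeights = DEFAULT_WEIGHTS,
    variant: str = VARIANT_ECC,
) -> CostValue:
    """Evaluate the weighted cost of a property-result set.

    Every property included by the (variant-adjusted) weights must have
    both a result and a target.  Results may carry raw values (MAPE is
    computed against the target here) or a precomputed MAPE.
    """
    if variant not in (VARIANT_ECC, VARIANT_GENERAL):
        raise ValueError(f"unknown variant {variant!r}")
    eff = weights
    if variant == VARIANT_GENERAL:
        drop = [n for n in _GENERAL_EXCLUDES if n in weights.included]
        if drop:
            eff = renormalize_weights(weights, drop)
    norm = eff.normalized()

    breakdown: Dict[str, float] = {}
    total = 0.0
    for name, w in norm.items():
        if name not in results:
            raise KeyError(f"missing property result: {name!r}")
        res = results[name]
        if res.mape_percent is not None:
            err = res.mape_percent
        else:
            if name not in targets:
                raise KeyError(f"missing property target: {name!r}")
            err = mape(res.values_array(), targets[name].values_array())
        loss = err / LOSS_SCALE_PERCENT
        breakdown[name] = loss
        total += w * loss
    return CostValue(total=total, variant=variant, breakdown=breakdown)


def is_better(candidate_cost: CostValue, incumbent_cost: CostValue) -> bool:
    """Strict improvement rule: lower cost wins, ties keep the incumbent."""
    if candidate_cost.variant != incumbent_cost.variant:
        raise ValueError(
            f"cannot compare variants {candidate_cost.variant!r} and {incumbent_cost.variant!r}"
        )
    return candidate_cost.total < incumbent_cost.total
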