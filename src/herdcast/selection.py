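"""Selection-response calculations: heritability, differential, effect.

Heritability is estimated from dam-offspring resemblance as h2 = 2 * r
(the additive expectation for a single-parent/offspring correlation),
clipped to [0, 1]. The per-generation selection effect follows the breeder's
equation SE = S * h2, with S the selection differential (mean of selected
parents minus population mean). Effects on slaughter indices are obtained by
propagating the live-weight effect through the trait-on-live-weight
regression coefficient: SE_target = b * SE_liveweight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .biometrics import CorrelationEstimate, InsufficientDataError, correlation_from_arrays
from .forecasting import RegressionCoefficient
from .herd_data import DAM_WEIGHT, LIVE_WEIGHT, HerdDataset, TraitKey

__all__ = [
    "HeritabilityEstimate",
    "SelectionEffect",
    "PropagatedEffect",
    "estimate_heritability",
    "selection_differential",
    "selection_effect",
    "propagate_effect",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    age_months: Optional[int]
    h2: float
    r_parent_offspring: float
    n: int
    correlation: CorrelationEstimate


@dataclass(frozen=True)
class SelectionEffect:
    """Expected per-generation change of a trait under the breeder's equation."""

    trait: str
    selection_differential: float
    h2_used: float
    effect_per_generation: float


@dataclass(frozen=True)
class PropagatedEffect:
    source_trait: str
    target: str
    b_target_on_source: float
    effect_target: float


def estimate_heritability(
    dataset: HerdDataset, trait: str = LIVE_WEIGHT, age_months: Optional[int] = 0, alpha: float = 0.05
) -> HeritabilityEstimate:
    """h2 = 2 * r(dam live weight, offspring trait), clipped to [0, 1].

    Uses the dam's live weight as the maternal productivity record, paired
    with each offspring's value of ``trait`` at ``age_months``.
    """
    dam = dataset.trait_values(DAM_WEIGHT)
    off = dataset.trait_values((trait, age_months))
    joined = dam.to_frame("dam").join(off.to_frame("off"), how="inner").dropna()
    if len(joined) < 4:
        raise InsufficientDataError(
            f"need >= 4 dam-offspring pairs for {trait}@{age_months}, have {len(joined)}"
        )
    est = correlation_from_arrays(
        joined["dam"].to_numpy(), joined["off"].to_numpy(), DAM_WEIGHT, (trait, age_months), alpha
    )
    raw = 2.0 * est.r
    if raw < 0.0 or raw > 1.0:
        warnings.warn(
            f"2*r(dam, offspring) = {raw:.3f} outside [0, 1]; clipping", stacklevel=2
        )
    return HeritabilityEstimate(
        trait=trait,
        age_months=age_months,
        h2=float(np.clip(raw, 0.0, 1.0)),
        r_parent_offspring=est.r,
        n=est.n,
        correlation=est,
    )


def selection_differential(
    dataset: HerdDataset,
    trait: str = LIVE_WEIGHT,
    age_months: Optional[int] = 0,
    top_fraction: Optional[float] = None,
    parent_ids: Optional[Iterable[str]] = None,
) -> float:
    """S = mean(selected parents) - mean(population) for one trait.

    Select either the top ``top_fraction`` of the trait distribution or an
    explicit ``parent_ids`` set; the selection must be a non-empty proper
    subset.
    """
    values = dataset.trait_values((trait, age_months))
    if len(values) == 0:
        raise InsufficientDataError(f"no values for {trait}@{age_months}")
    if (top_fraction is None) == (parent_ids is None):
        raise ValueError("give exactly one of top_fraction or parent_ids")
    if parent_ids is not None:
        selected = values.loc[values.index.intersection(list(parent_ids))]
    else:
        if not 0.0 < top_fraction < 1.0:
            raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
        k = int(np.ceil(top_fraction * len(values)))
        selected = values.nlargest(k)
    if len(selected) == 0 or len(selected) == len(values):
        raise ValueError(
            f"selection must be a non-empty proper subset (selected {len(selected)} of {len(values)})"
        )
    return float(selected.mean() - values.mean())


def selection_effect(differential: float, h2: HeritabilityEstimate | float, trait: str = LIVE_WEIGHT) -> SelectionEffect:
    """Breeder's equation: per-generation effect = differential * h2."""
    if isinstance(h2, HeritabilityEstimate):
        h2_value, trait = h2.h2, h2.trait
    else:
        h2_value = float(h2)
    if not 0.0 <= h2_value <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2_value}")
    return SelectionEffect(
        trait=trait,
        selection_differential=float(differential),
        h2_used=h2_value,
        effect_per_generation=float(differential) * h2_value,
    )


def propagate_effect(effect_liveweight: SelectionEffect, b: RegressionCoefficient) -> PropagatedEffect:
    """Carry a live-weight selection effect onto a slaughter index via its b.

    The proportion: if live weight shifts by SE per generation and the
    slaughter index changes by b per kg of live weight, the index shifts by
    b * SE.
    """
    if effect_liveweight.trait != LIVE_WEIGHT:
        raise ValueError(f"selection effect is for {effect_liveweight.trait!r}, expected live weight")
    if b.marker[0] != LIVE_WEIGHT:
        raise ValueError(f"regression coefficient marker is {b.marker}, expected live weight")
    return PropagatedEffect(
        source_trait=effect_liveweight.trait,
        target=b.target,
        b_target_on_source=b.b,
        effect_target=b.b * effect_liveweight.effect_per_generation,
    )
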