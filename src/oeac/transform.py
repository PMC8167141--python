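"""Species-aware log-linear age transformation.

Epigenetic clocks for long-lived mammals are usually trained not on
chronological age directly but on a transformed age that is logarithmic
before sexual maturity (when methylation change is fast) and linear
afterwards.  The transform used here is parameterised by two life-history
traits of each species: the average age at sexual maturity ``m`` (years)
and the gestation time ``g`` (years).  With ``k = m + g``,

    F(x) = log((x + g) / k)   for 0 <= x <= m
    F(x) = (x - m) / k        for x > m

``F`` is strictly increasing, satisfies ``F(m) = 0`` and is continuously
differentiable at the knot (both one-sided derivatives equal ``1/k``), so
the regression target changes smoothly from the juvenile to the adult
regime.  The exact inverse maps a clock's linear predictor back to years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeTransform", "transform_age", "inverse_transform_age"]


@dataclass(frozen=True)
class AgeTransform:
    """Log-linear age transform for one species.

    Parameters
    ----------
    asm_years : float
        Average age at sexual maturity ``m``, in years. Must be positive.
    gestation_years : float
        Gestation time ``g``, in years. Must be positive.

    Attributes
    ----------
    scale : float
        The derived scale ``k = m + g`` (years), the slope reciprocal of
        the adult branch.
    """

    asm_years: float
    gestation_years: float
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.asm_years > 0:
            raise ValueError(f"asm_years must be > 0, got {self.asm_years}")
        if not self.gestation_years > 0:
            raise ValueError(
                f"gestation_years must be > 0, got {self.gestation_years}"
            )
        object.__setattr__(self, "scale", self.asm_years + self.gestation_years)

    def __call__(self, age_years):
        return transform_age(age_years, self)

    def inverse(self, y):
        return inverse_transform_age(y, self)


def transform_age(age_years, params: AgeTransform):
    """Map chronological age (years) to the unitless transformed scale.

    Accepts a scalar or array; ages must be non-negative.
    """
    x = np.asarray(age_years, dtype=float)
    if np.any(x < 0):
        raise ValueError("chronological age must be non-negative")
    m, g, k = params.asm_years, params.gestation_years, params.scale
    out = np.where(x <= m, np.log((x + g) / k), (x - m) / k)
    if np.isscalar(age_years) or np.ndim(age_years) == 0:
        return float(out)
    return out

def inverse_transform_age(y, params: AgeTransform):
    """Map a transformed-age value back to years, clipping below at 0.

    Exact inverse of :func:`transform_age` on the non-clipped domain; any
    input real is accepted (a clock's linear predictor can undershoot the
    transform's range, which corresponds to a negative age and is clipped).
    """
    yv = np.asarray(y, dtype=float)
    m, g, k = params.asm_years, params.gestation_years, params.scale
    out = np.where(yv <= 0, k * np.exp(yv) - g, m + k * yv)
    out = np.clip(out, 0.0, None)
    if np.isscalar(y) or np.ndim(y) == 0:
        return float(out)
    return out
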