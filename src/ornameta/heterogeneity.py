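"""Heterogeneity partitioning (multilevel I²) and marginal R².

Multilevel I² expresses each estimated variance component as a percentage of
the total variance, where the total adds the "typical" sampling variance
``s̄²`` — a weighted summary of the per-effect sampling variances — to the sum
of the estimated components.  Marginal R² is the share of variance explained
by the fixed moderators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .model import FitResult, ModelError


@dataclass
class HeterogeneityResult:
    s2_typical: float
    i2_total: float  # percent
    i2_by_component: dict[str, float]  # percent
    boundary_components: list[str]  # components estimated exactly at zero

    def to_dict(self) -> dict:
        return {
            "s2_typical": self.s2_typical,
            "i2_total": round(self.i2_total, 1),
            "i2_by_component": {
                k: round(v, 1) for k, v in self.i2_by_component.items()
            },
            "boundary_components": self.boundary_components,
        }


def typical_sampling_variance(v) -> float:
    """Typical sampling variance ``s̄² = (k-1) Σw / ((Σw)² - Σw²)``, w = 1/v.

    Collapses to ``c`` when all sampling variances equal ``c``; scales
    linearly with a common rescaling of the ``v``.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ModelError("typical sampling variance needs k >= 2")
    if np.any(v <= 0):
        raise ModelError("sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    return float((v.size - 1) * sw / (sw**2 - (w**2).sum()))


def i2_partition(fit: FitResult, dataset: Dataset | None = None) -> HeterogeneityResult:
    """Partition total heterogeneity across the fit's random components.

    ``I²_u = 100 σ̂²_u / (Σ σ̂² + s̄²)``; components sum to the total by
    construction.  Uses the sampling variances the model was fitted with
    (diagonal only; any within-experiment correlation used in fitting is
    ignored here, as is standard).
    """
    if not fit.sigma2:
        raise ModelError("fit has no random components to partition")
    s2_typ = typical_sampling_variance(fit.v)
    total_s2 = sum(fit.sigma2.values())
    denom = total_s2 + s2_typ
    by_comp = {nm: 100.0 * s2 / denom for nm, s2 in fit.sigma2.items()}
    boundary = [nm for nm, s2 in fit.sigma2.items() if s2 == 0.0]
    return HeterogeneityResult(
        s2_typical=s2_typ,
        i2_total=100.0 * total_s2 / denom,
        i2_by_component=by_comp,
        boundary_components=boundary,
    )


def marginal_r2(fit: FitResult, dataset: Dataset | None = None) -> float:
    """Variance explained by the fixed effects:
    ``R² = σ²_f / (σ²_f + Σ σ̂²_u)`` with ``σ²_f`` the population variance of
    the fitted linear predictor.  Returns 0 for an intercept-only fit."""
    if fit.p_fixed == 1 and fit.beta_names == ["intercept"]:
        return 0.0
    s2_f = float(np.var(fit.fitted))  # population variance (divide by k)
    denom = s2_f + sum(fit.sigma2.values())
    if denom == 0:
        return 0.0
    return s2_f / denom
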