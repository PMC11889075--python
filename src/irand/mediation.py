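"""Mediation decomposition: total, natural direct, and natural indirect effects.

Under a linear outcome model with no treatment–mediator interaction the
total causal effect decomposes additively::

    total effect = direct effect + indirect effect

The total effect is estimated by I-Rand matching on the confounders alone;
the direct effect by adding the mediator to the matching set (stratifying on
the mediator closes the mediated path, and matching the confounders closes
the back-door paths that conditioning on a collider-like mediator opens).
The indirect effect is their difference, computed subsample-by-subsample and
permutation-by-permutation, which both enforces the decomposition identity
exactly and yields a permutation p-value for the indirect effect.

The two I-Rand runs must share subsample assignments and permutation draws;
running them with the same seed guarantees this (the estimator derives both
streams from (seed, subsample index) only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IRandError, SeedContractError
from .irand import IRandResult, irand_estimate, summarize_pvalues
from .panel import TwoPointPanel

__all__ = [
    "MediationSpec",
    "MediationResult",
    "total_effect",
    "direct_effect",
    "indirect_effect",
    "mediation_analysis",
    "bmi_category",
    "BMI_CUTS",
]

#: BMI category boundaries: normal <25, overweight [25,30), obese [30,35),
#: severely obese >=35
BMI_CUTS = (25.0, 30.0, 35.0)


def bmi_category(bmi) -> np.ndarray:
    """Ordinal BMI category codes 0..3 from continuous BMI."""
    return np.digitize(np.asarray(bmi, dtype=float), BMI_CUTS)


@dataclass
class MediationSpec:
    """Variable roles and run parameters for a mediation analysis.

    ``contrast`` optionally names two adjacent ordinal treatment levels
    (lower, higher); each subsample is then restricted to units at those two
    levels, the higher level coded as treated.
    """

    treatment: str
    outcome: str
    mediator: str
    confounders: list[str]
    M: int = 500
    S: int = 200
    seed: int | None = None
    scheme: str = "iid"
    contrast: tuple | None = None

    def __post_init__(self):
        if self.mediator in self.confounders:
            raise IRandError("mediator must not be listed among the confounders")
        if self.contrast is not None and self.contrast[0] == self.contrast[1]:
            raise IRandError("contrast pair must name two distinct levels")


@dataclass
class MediationResult:
    """Total / direct / indirect estimates with per-subsample detail.

    ``residual`` is total − direct − indirect and is zero by construction.
    """

    total: IRandResult
    direct: IRandResult
    indirect_ates: np.ndarray
    indirect_estimate: float
    indirect_pvalues: np.ndarray
    residual: float

    def summary(self, alpha: float = 0.05) -> dict:
        out = {
            "total": self.total.estimate,
            "direct": self.direct.estimate,
            "indirect": self.indirect_estimate,
            "residual": self.residual,
        }
        if self.total.S >= 1:
            out["total_p"] = summarize_pvalues(self.total, alpha)
            out["direct_p"] = summarize_pvalues(self.direct, alpha)
            fake = _PvalueCarrier(self.indirect_pvalues)
            out["indirect_p"] = summarize_pvalues(fake, alpha)
        return out


class _PvalueCarrier:
    def __init__(self, pvalues):
        self.pvalues = pvalues


def total_effect(panel: TwoPointPanel, spec: MediationSpec) -> IRandResult:
    """Total causal effect: I-Rand with the confounders as the matching set."""
    return irand_estimate(
        panel, M=spec.M, S=spec.S, scheme=spec.scheme, seed=spec.seed,
        treatment=spec.treatment, outcome=spec.outcome,
        confounders=spec.confounders, contrast=spec.contrast)


def direct_effect(panel: TwoPointPanel, spec: MediationSpec) -> IRandResult:
    """Natural direct effect: the mediator joins the matching covariates."""
    if spec.mediator not in panel.data.columns:
        raise IRandError(f"mediator column {spec.mediator!r} not in panel")
    return irand_estimate(
        panel, M=spec.M, S=spec.S, scheme=spec.scheme, seed=spec.seed,
        treatment=spec.treatment, outcome=spec.outcome,
        confounders=list(spec.confounders) + [spec.mediator],
        contrast=spec.contrast)


def indirect_effect(total: IRandResult, direct: IRandResult) -> MediationResult:
    """Indirect effect by differencing, subsample- and permutation-wise.

    Requires that ``total`` and ``direct`` were run on identical subsample
    assignments and permutation draws (same seed); otherwise raises
    :class:`SeedContractError`.
    """
    if total.assignments.shape != direct.assignments.shape or not np.array_equal(
            total.assignments, direct.assignments):
        raise SeedContractError(
            "total and direct runs used different subsample assignments; "
            "run both with the same seed")
    ind_ates = total.ates - direct.ates
    estimate = float(ind_ates.mean())
    if total.S >= 1 and total.perm_ates.shape == direct.perm_ates.shape:
        ind_perm = total.perm_ates - direct.perm_ates
        S = ind_perm.shape[1]
        hits = np.sum(np.abs(ind_perm) >= np.abs(ind_ates)[:, None] - 1e-12, axis=1)
        pvalues = (1.0 + hits) / (S + 1.0)
    else:
        pvalues = np.empty(0)
    residual = float(total.estimate - direct.estimate - estimate)
    return MediationResult(
        total=total, direct=direct, indirect_ates=ind_ates,
        indirect_estimate=estimate, indirect_pvalues=pvalues,
        residual=residual)


def mediation_analysis(panel: TwoPointPanel, spec: MediationSpec) -> MediationResult:
    """Convenience wrapper: total, direct, and indirect in one call."""
    tot = total_effect(panel, spec)
    dirr = direct_effect(panel, spec)
    return indirect_effect(tot, dirr)
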