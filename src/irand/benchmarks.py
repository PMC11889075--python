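"""Benchmark estimators for two-visit panels.

* :func:`pooled_ate` — stack both visits into one 2n-row cross-section and
  match on the confounders (time is not a matching covariate).  Simple, but
  each individual contributes two rows, so when treatment is determined by
  time the two rows interfere and no-interference fails.
* :func:`did_stacked_lcd` — difference-in-differences for the all-treated
  follow-up design.  Without an untreated group, P(DT=1|X)=1 and matching on
  the differenced data is impossible; a synthetic control group is stacked
  from the baseline rows (DY = Y_0, DT = 0) against the differenced treated
  rows (DY = Y_1 − Y_0, DT = 1, covariates DX).
* :func:`did_bmi_like` — difference-in-differences when treatment can switch
  either way between visits: the four treatment-history groups are formed,
  treated-to-untreated and always-treated are dropped, and the
  untreated-to-treated group is matched against the never-treated on
  baseline covariates with outcome DY.
* :func:`did_firstdiff` — first-difference analysis with derived threshold
  treatments and, where everyone is treated, a hypothetical zero-outcome
  control group; inference by permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DesignError, GroupError, PositivityError
from .irand import _permutation_pvalue_rng
from .matching import _ate_core
from .panel import TwoPointPanel

__all__ = [
    "pooled_ate",
    "did_stacked_lcd",
    "did_bmi_like",
    "did_firstdiff",
    "difference_sample",
    "GROUP_LABELS",
]

#: treatment-history taxonomy keyed by (T at visit 0, T at visit 1)
GROUP_LABELS = {
    (1, 1): "always",
    (0, 0): "never",
    (1, 0): "treated_to_untreated",
    (0, 1): "untreated_to_treated",
}


def _panel_arrays(panel, treatment, outcome, confounders):
    T0, T1 = panel.column_pair(treatment)
    Y0, Y1 = (np.asarray(v, float) for v in panel.column_pair(outcome))
    X0, X1 = panel.arrays(confounders)
    return np.asarray(T0), np.asarray(T1), Y0, Y1, X0, X1


def _confounders(panel, confounders):
    if confounders is not None:
        return list(confounders)
    cols = panel.meta.get("confounders")
    if cols:
        return list(cols)
    raise ValueError("confounder columns must be given")


def difference_sample(
    panel: TwoPointPanel,
    treatment: str = "treatment",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual differenced table: DY, DT, DX, baselines, group label."""
    confounders = _confounders(panel, confounders)
    T0, T1, Y0, Y1, X0, X1 = _panel_arrays(panel, treatment, outcome, confounders)
    df = pd.DataFrame({"id": panel.ids, "DY": Y1 - Y0,
                       "DT": T1.astype(int) - T0.astype(int),
                       "Y0": Y0, "T0": T0, "T1": T1})
    for j, c in enumerate(confounders):
        df[f"D_{c}"] = X1[:, j] - X0[:, j]
        df[f"{c}_0"] = X0[:, j]
    df["group"] = [GROUP_LABELS[(int(a), int(b))] for a, b in zip(T0, T1)]
    return df


def pooled_ate(
    panel: TwoPointPanel,
    treatment: str = "treatment",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
) -> float:
    """Matched ATE on the pooled 2n-row sample (both visits stacked)."""
    confounders = _confounders(panel, confounders)
    T0, T1, Y0, Y1, X0, X1 = _panel_arrays(panel, treatment, outcome, confounders)
    T = np.concatenate([T0, T1]).astype(float)
    Y = np.concatenate([Y0, Y1])
    X = np.vstack([X0, X1])
    if T.min() == T.max():
        raise PositivityError("pooled sample has a single treatment class")
    return _ate_core(X, T, Y)


def did_stacked_lcd(
    panel: TwoPointPanel,
    treatment: str = "treatment",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
) -> float:
    """Difference-in-differences with a stacked synthetic control group.

    Requires the all-treated-at-follow-up design (T=0 at visit 0, T=1 at
    visit 1 for everyone).  Control rows carry the baseline outcome and
    baseline covariates; treated rows carry the differenced outcome and
    differenced covariates, exactly as the stacked construction defines
    them.
    """
    confounders = _confounders(panel, confounders)
    T0, T1, Y0, Y1, X0, X1 = _panel_arrays(panel, treatment, outcome, confounders)
    if not (np.all(T0 == 0) and np.all(T1 == 1)):
        raise DesignError(
            "stacked-synthetic-control DiD needs the all-treated-at-follow-up "
            "design (T=0 at baseline, T=1 at follow-up for every individual)")
    DY = np.concatenate([Y0, Y1 - Y0])
    DT = np.concatenate([np.zeros(panel.n), np.ones(panel.n)])
    DX = np.vstack([X0, X1 - X0])
    return _ate_core(DX, DT, DY)


def did_bmi_like(
    panel: TwoPointPanel,
    treatment: str = "treatment",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
) -> float:
    """Group-construction DiD for treatments that can switch either way.

    Keeps only never-treated (control) and untreated-to-treated (treated)
    individuals, uses DY as the outcome and the baseline covariates for
    matching.  Raises :class:`GroupError` when a required group is empty.
    """
    confounders = _confounders(panel, confounders)
    T0, T1, Y0, Y1, X0, X1 = _panel_arrays(panel, treatment, outcome, confounders)
    never = (T0 == 0) & (T1 == 0)
    u2t = (T0 == 0) & (T1 == 1)
    for mask, name in ((never, "never-treated"), (u2t, "untreated-to-treated")):
        if not mask.any():
            raise GroupError(f"required group '{name}' is empty")
    keep = never | u2t
    DY = (Y1 - Y0)[keep]
    T = u2t[keep].astype(float)
    X = X0[keep]
    return _ate_core(X, T, DY)


def did_firstdiff(
    panel: TwoPointPanel,
    treatment_rule: str = "delta_lcd",
    rule_column: str = "bmi",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
    S: int = 200,
    seed: int | None = None,
) -> tuple[float, float]:
    """First-difference analysis with a derived treatment (ATE, p-value).

    Differences every variable between visits; confounders are the baseline
    values.  Treatment rules:

    ``delta_lcd``
        everyone treated (the diet started between visits); an equal-size
        hypothetical control group with zero outcome and confounders
        bootstrap-resampled from the observed baselines is appended, so the
        ATE reduces to a matched mean of the observed outcome changes.
    ``delta_bmi_negative``
        treated iff the rule column decreased; because almost everyone's
        value decreases in the data this emulates, the same hypothetical
        control group is appended.
    ``delta_bmi_below_median``
        treated iff the decrease exceeds the median magnitude of change,
        i.e. Δ < −median|Δ|; splits an all-decreasing sample into
        equal-sized groups, no hypothetical controls needed.

    The p-value permutes the treatment labels of the assembled
    cross-section (counts preserved) and recomputes the matched ATE.
    """
    confounders = _confounders(panel, confounders)
    _, _, Y0, Y1, X0, _ = _panel_arrays(panel, "visit", outcome, confounders)
    DY = Y1 - Y0
    n = panel.n
    rng = np.random.default_rng(seed)

    if treatment_rule == "delta_lcd":
        T_real = np.ones(n)
    elif treatment_rule in ("delta_bmi_negative", "delta_bmi_below_median"):
        r0, r1 = (np.asarray(v, float) for v in panel.column_pair(rule_column))
        d = r1 - r0
        if treatment_rule == "delta_bmi_negative":
            T_real = (d < 0).astype(float)
        else:
            mag = np.median(np.abs(d))
            if np.ptp(d) == 0:
                raise DesignError("rule column change is constant; median split undefined")
            T_real = (d < -mag).astype(float)
    else:
        raise ValueError(f"unknown treatment rule {treatment_rule!r}")

    X = X0
    Y = DY
    T = T_real
    if treatment_rule in ("delta_lcd", "delta_bmi_negative"):
        # hypothetical zero-outcome controls restore positivity
        boot = rng.integers(0, n, size=n)
        X = np.vstack([X0, X0[boot]])
        Y = np.concatenate([DY, np.zeros(n)])
        T = np.concatenate([T_real, np.zeros(n)])
    if T.min() == T.max():
        raise PositivityError("derived treatment has a single class")
    ate = _ate_core(X, T, Y)
    pval, _ = _permutation_pvalue_rng(X, T, Y, ate, S, rng)
    return ate, pval
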