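"""The subsample-randomization (I-Rand) estimator.

For a two-visit panel with no control group, draw M subsamples that contain
every individual exactly once — at the baseline or the follow-up visit —
compute a propensity-matched ATE on each subsample, and average:

.. math:: \\widehat{ATE} = \\frac{1}{M}\\sum_{m=1}^M ATE^{(m)}.

Subsampling one visit per individual creates a synthetic mix of treated and
untreated observations even when treatment is determined by time, restoring
positivity without violating no-interference (each individual contributes
one observation per subsample).  Significance is assessed per subsample by a
permutation test: the treatment vector is shuffled (treated count preserved),
the propensity model refit, the sample rematched, and the ATE recomputed;
the p-value is the smoothed fraction of shuffles whose |ATE| reaches the
observed |ATE|.  Because subsamples overlap, the M p-values are dependent;
results are therefore summarized as a distribution (median, fraction below
alpha) rather than combined into a single number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import PositivityError
from .matching import _ate_core
from .panel import TwoPointPanel

__all__ = [
    "draw_subsamples",
    "subsample_ate",
    "permutation_pvalue",
    "irand_estimate",
    "summarize_pvalues",
    "IRandResult",
]

log = logging.getLogger(__name__)

# fixed stream tags so that runs with the same seed draw identical
# assignments and shuffles regardless of which covariates are matched on
# (the mediation decomposition depends on this)
_STREAM_ASSIGN = 3
_STREAM_PERM = 7
_STREAM_REDRAW = 11


@dataclass
class IRandResult:
    """Result bundle of one I-Rand run.

    ``estimate`` is exactly the mean of ``ates``; ``pvalues[m]`` is the
    permutation p-value of subsample m (empty when S=0); ``perm_ates`` holds
    the (M, S) permuted ATEs so downstream decompositions can reuse the same
    permutation draws; ``assignments`` is the (M, n) matrix of chosen visits.
    """

    ates: np.ndarray
    estimate: float
    pvalues: np.ndarray
    perm_ates: np.ndarray
    assignments: np.ndarray
    M: int
    S: int
    seed: int | None
    scheme: str

    def summary(self, alpha: float = 0.05) -> dict:
        return summarize_pvalues(self, alpha)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "M": self.M,
            "S": self.S,
            "seed": self.seed,
            "scheme": self.scheme,
            "ates": self.ates.tolist(),
            "pvalues": self.pvalues.tolist(),
        }


def draw_subsamples(
    panel: TwoPointPanel | int,
    M: int,
    scheme: str = "iid",
    seed: int | None = None,
) -> np.ndarray:
    """Draw M visit assignments, one visit per individual per subsample.

    Returns an (M, n) integer matrix of chosen visits.  ``iid``: each visit
    chosen independently with probability 1/2.  ``balanced``: per individual,
    a random permutation of floor(M/2) zeros and the rest ones across the M
    subsamples, which minimizes pairwise subsample overlap (the
    Latin-hypercube-style option); with odd M the split rounds, noted in the
    log.
    """
    n = panel if isinstance(panel, int) else panel.n
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([_seed_entropy(seed), _STREAM_ASSIGN]))
    if scheme == "iid":
        return rng.integers(0, 2, size=(M, n), dtype=np.int8)
    if scheme == "balanced":
        if M % 2:
            log.info("balanced scheme with odd M=%d: %d zeros, %d ones per individual",
                     M, M // 2, M - M // 2)
        base = np.ones(M, dtype=np.int8)
        base[: M // 2] = 0
        cols = [rng.permutation(base) for _ in range(n)]
        return np.column_stack(cols)
    raise ValueError(f"unknown subsampling scheme {scheme!r}")


def _seed_entropy(seed) -> int:
    return 0 if seed is None else int(seed)


class _PanelArrays:
    """Pre-extracted per-visit arrays for the hot loops."""

    def __init__(self, panel: TwoPointPanel, treatment: str, outcome: str,
                 confounders: list[str]):
        self.T0, self.T1 = (np.asarray(v, dtype=float) for v in panel.column_pair(treatment))
        self.Y0, self.Y1 = (np.asarray(v, dtype=float) for v in panel.column_pair(outcome))
        self.X0, self.X1 = panel.arrays(confounders)
        self.n = panel.n

    def cross_section(self, visits: np.ndarray):
        pick = visits.astype(bool)
        T = np.where(pick, self.T1, self.T0)
        Y = np.where(pick, self.Y1, self.Y0)
        X = np.where(pick[:, None], self.X1, self.X0)
        return X, T, Y


def _resolve_confounders(panel: TwoPointPanel, confounders) -> list[str]:
    if confounders is not None:
        return list(confounders)
    inferred = panel.meta.get("confounders")
    if inferred:
        return list(inferred)
    raise ValueError("confounder columns must be given (none recorded in panel meta)")


def _apply_contrast(X, T, Y, contrast):
    """Restrict to units whose treatment value is in the contrast pair and
    binarize (higher level = treated)."""
    lo, hi = contrast
    if lo == hi:
        raise ValueError("contrast pair must name two distinct levels")
    keep = (T == lo) | (T == hi)
    return X[keep], (T[keep] == hi).astype(float), Y[keep]


def subsample_ate(
    panel: TwoPointPanel,
    assignment: np.ndarray,
    treatment: str = "treatment",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
    contrast: tuple | None = None,
    seed: int | None = None,
    bias_adjust: bool = True,
) -> float:
    """Matched ATE of the cross-section picked out by one visit assignment.

    If the drawn cross-section has a single treatment class, one fresh
    assignment is drawn (seeded); a second failure raises
    :class:`PositivityError`.
    """
    cols = _resolve_confounders(panel, confounders)
    arrays = _PanelArrays(panel, treatment, outcome, cols)
    ate, _ = _subsample_ate_arrays(arrays, np.asarray(assignment), contrast,
                                   np.random.default_rng(seed), bias_adjust)
    return ate


def _subsample_ate_arrays(arrays, visits, contrast, redraw_rng, bias_adjust=True):
    X, T, Y = arrays.cross_section(visits)
    if contrast is not None:
        X, T, Y = _apply_contrast(X, T, Y, contrast)
    if len(T) == 0 or T.min() == T.max():
        log.warning("one-class subsample; redrawing the visit assignment once")
        visits = redraw_rng.integers(0, 2, size=arrays.n)
        X, T, Y = arrays.cross_section(visits)
        if contrast is not None:
            X, T, Y = _apply_contrast(X, T, Y, contrast)
        if len(T) == 0 or T.min() == T.max():
            raise PositivityError("subsample has a single treatment class after redraw")
    return _ate_core(X, T, Y, bias_adjust=bias_adjust), (X, T, Y)


def permutation_pvalue(
    X: np.ndarray,
    T: np.ndarray,
    Y: np.ndarray,
    observed_ate: float,
    S: int,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for one cross-section.

    Each of S shuffles permutes the treatment vector uniformly (the treated
    count is preserved automatically), refits the propensity model,
    rematches, and recomputes the ATE.  Returns the add-one-smoothed
    two-sided p-value ``(1 + #{|ATE_s| >= |observed|}) / (S + 1)``, so p is
    always in (0, 1].
    """
    rng = np.random.default_rng(seed)
    p, _ = _permutation_pvalue_rng(X, T, Y, observed_ate, S, rng)
    return p


def _permutation_pvalue_rng(X, T, Y, observed_ate, S, rng, bias_adjust=True):
    perm_ates = np.empty(S)
    for s in range(S):
        Ts = rng.permutation(T)
        perm_ates[s] = _ate_core(X, Ts, Y, bias_adjust=bias_adjust)
    hits = int(np.sum(np.abs(perm_ates) >= abs(observed_ate) - 1e-12))
    return (1.0 + hits) / (S + 1.0), perm_ates


def irand_estimate(
    panel: TwoPointPanel,
    M: int = 500,
    S: int = 200,
    scheme: str = "iid",
    seed: int | None = None,
    treatment: str = "treatment",
    outcome: str = "outcome",
    confounders: list[str] | None = None,
    contrast: tuple | None = None,
    assignments: np.ndarray | None = None,
    bias_adjust: bool = True,
) -> IRandResult:
    """Full I-Rand pipeline on a two-visit panel.

    Draw M subsamples (or reuse ``assignments``), compute a matched ATE per
    subsample, average them, and — when S >= 1 — attach a permutation
    p-value per subsample.  Deterministic given seed; the permutation stream
    of subsample m depends only on (seed, m), never on the covariate set.
    """
    cols = _resolve_confounders(panel, confounders)
    arrays = _PanelArrays(panel, treatment, outcome, cols)
    if assignments is None:
        assignments = draw_subsamples(panel.n, M, scheme=scheme, seed=seed)
    else:
        assignments = np.asarray(assignments)
        M = assignments.shape[0]

    ates = np.empty(M)
    pvalues = np.empty(M if S >= 1 else 0)
    perm_ates = np.empty((M, S) if S >= 1 else (M, 0))
    ent = _seed_entropy(seed)
    for m in range(M):
        redraw_rng = np.random.default_rng(
            np.random.SeedSequence([ent, _STREAM_REDRAW, m]))
        try:
            ates[m], (X, T, Y) = _subsample_ate_arrays(
                arrays, assignments[m], contrast, redraw_rng, bias_adjust)
        except PositivityError as err:
            raise PositivityError(f"subsample {m}: {err}") from err
        if S >= 1:
            perm_rng = np.random.default_rng(
                np.random.SeedSequence([ent, _STREAM_PERM, m]))
            pvalues[m], perm_ates[m] = _permutation_pvalue_rng(
                X, T, Y, ates[m], S, perm_rng, bias_adjust)
    return IRandResult(
        ates=ates,
        estimate=float(ates.mean()),
        pvalues=pvalues,
        perm_ates=perm_ates,
        assignments=assignments,
        M=M,
        S=S,
        seed=seed,
        scheme=scheme,
    )


def summarize_pvalues(result: IRandResult, alpha: float = 0.05) -> dict:
    """Distribution summary of the per-subsample p-values.

    The package's rejection convention: reject the no-effect null at level
    ``alpha`` when the *median* subsample p-value is below ``alpha``.
    """
    p = np.asarray(result.pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("result carries no p-values (run with S >= 1)")
    q1, med, q3 = np.percentile(p, [25, 50, 75])
    return {
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(p.min()),
        "max": float(p.max()),
        "frac_below_alpha": float(np.mean(p < alpha)),
        "alpha": alpha,
        "reject": bool(med < alpha),
    }
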