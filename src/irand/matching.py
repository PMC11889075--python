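"""Propensity-score matching ATE estimation on a cross-section.

The pipeline is: fit a logistic propensity model of treatment on the
confounders, match every unit to its nearest opposite-group unit on the
fitted score (1-NN, with replacement, in *both* directions), impute each
unit's missing potential outcome from its match with a regression bias
correction, and average the imputed individual effects over all units.
Matching both directions targets the ATE (not the ATT).  The bias
correction (within-group linear outcome regressions evaluated at the unit's
and the match's covariates) removes the first-order error from the
covariate discrepancy between a unit and its nearest neighbour — without
it, one-dimensional score matching leaves an O(n^{-1/2}) covariate
imbalance whose bias dominates the estimator whenever the outcome depends
strongly on a confounder.

The logistic fit is a small Newton/IRLS solver written directly on numpy
arrays: the subsample-randomization estimator refits the propensity model
inside every subsample and every permutation shuffle, so per-call overhead
matters far more than it would for a single fit.  The solver is validated
against an external maximum-likelihood fit in the test suite.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import PositivityError
from .panel import CrossSection

__all__ = ["fit_propensity", "match_units", "matched_ate", "estimate_ate", "MatchResult"]

log = logging.getLogger(__name__)

_MAX_ITER = 60
_TOL = 1e-10
_warned_separation = False
#: ridge used to re-stabilize the fit under (quasi-)separation
_SEPARATION_RIDGE = 1e-2


def _logit_fit(X: np.ndarray, T: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Newton/IRLS maximum-likelihood logistic fit of T on [1, X].

    Returns the coefficient vector (intercept first).  Columns with zero
    variance are dropped internally (their weight folds into the intercept),
    so an all-constant X degrades gracefully to the intercept-only fit.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    keep = X.std(axis=0) > 0
    Xk = X[:, keep]
    n, k = Xk.shape
    A = np.column_stack([np.ones(n), Xk])
    beta = np.zeros(k + 1)
    beta[0] = _logit_of_mean(T)
    eye = np.eye(k + 1)
    for _ in range(_MAX_ITER):
        eta = A @ beta
        p = _expit(eta)
        w = p * (1.0 - p)
        grad = A.T @ (T - p) - ridge * beta
        hess = (A * w[:, None]).T @ A + (ridge + 1e-12) * eye
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - hess regularized above
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            break
        if np.max(np.abs(step)) < _TOL:
            full = np.zeros(X.shape[1] + 1)
            full[0] = beta[0]
            full[1:][keep] = beta[1:]
            return full
    if ridge == 0.0:
        # non-convergence almost always means (quasi-)separation; the ridge
        # pulls the scores off the 0/1 boundary while keeping the ordering
        global _warned_separation
        if not _warned_separation:
            log.warning("propensity fit did not converge (likely separation); "
                        "refitting with ridge %g (warned once per process)",
                        _SEPARATION_RIDGE)
            _warned_separation = True
        return _logit_fit(X, T, ridge=_SEPARATION_RIDGE)
    full = np.zeros(X.shape[1] + 1)
    full[0] = beta[0]
    full[1:][keep] = beta[1:]
    return full


def _expit(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _logit_of_mean(T):
    m = min(max(T.mean(), 1e-9), 1 - 1e-9)
    return np.log(m / (1 - m))


def _propensity_scores(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    if T.min() == T.max():
        raise PositivityError("cross-section has a single treatment class")
    beta = _logit_fit(X, T)
    scores = _expit(np.column_stack([np.ones(len(T)), X]) @ beta)
    # keep scores strictly inside (0,1)
    return np.clip(scores, 1e-12, 1 - 1e-12)


def fit_propensity(cs: CrossSection) -> np.ndarray:
    """Fitted propensity scores P(T=1|X), strictly in (0,1).

    Maximum-likelihood logistic regression with intercept; by the logistic
    score equation the mean fitted score equals the treated fraction.
    Perfect separation is handled by a ridge-stabilized refit (logged).
    """
    return _propensity_scores(cs.X, cs.T)


def _nearest_opposite(scores: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Index of the nearest opposite-group unit for every unit.

    Nearest by absolute score distance; ties broken by the lowest unit
    index among all equidistant candidates.
    """
    n = len(T)
    partner = np.empty(n, dtype=np.int64)
    for group in (0, 1):
        q = np.flatnonzero(T == group)           # units needing a match
        cand = np.flatnonzero(T != group)        # opposite-group candidates
        if len(cand) == 0:
            raise PositivityError("no opposite-group units to match against")
        order = np.argsort(scores[cand], kind="stable")
        s = scores[cand][order]                  # sorted candidate scores
        idx = cand[order]                        # original indices, sorted by score
        pos = np.searchsorted(s, scores[q])
        left = np.clip(pos - 1, 0, len(s) - 1)
        right = np.clip(pos, 0, len(s) - 1)
        dl = np.abs(scores[q] - s[left])
        dr = np.abs(s[right] - scores[q])
        # out-of-range sides get infinite distance
        dl = np.where(pos == 0, np.inf, dl)
        dr = np.where(pos == len(s), np.inf, dr)
        # first occurrence of each candidate value -> lowest index in a
        # run of equal scores (argsort is stable, so runs keep id order)
        lstart = np.searchsorted(s, s[left], side="left")
        rstart = np.searchsorted(s, s[right], side="left")
        pick_left = idx[lstart]
        pick_right = idx[rstart]
        chosen = np.where(dl < dr, pick_left,
                          np.where(dr < dl, pick_right,
                                   np.minimum(pick_left, pick_right)))
        partner[q] = chosen
    return partner


def match_units(scores: np.ndarray, T: np.ndarray,
                caliper: float | None = None) -> np.ndarray:
    """1-nearest-neighbour match on the propensity score, with replacement.

    Every unit (treated and control) is matched to the closest unit of the
    opposite group.  Returns the partner index array.  With ``caliper``
    (off by default), units whose nearest opposite score is farther than
    the caliper are left unmatched (partner −1) and are skipped by
    :func:`matched_ate`.
    """
    scores = np.asarray(scores, dtype=float)
    T = np.asarray(T, dtype=int)
    pairs = _nearest_opposite(scores, T)
    if caliper is not None:
        pairs = np.where(np.abs(scores - scores[pairs]) <= caliper, pairs, -1)
    return pairs


def matched_ate(cs: CrossSection, pairs: np.ndarray, bias_adjust: bool = False) -> float:
    """ATE from matched pairs: impute each unit's missing potential outcome
    from its opposite-group match and average Y(1)−Y(0) over all units.

    With ``bias_adjust=True`` the imputations carry the regression
    bias correction described in :func:`_ate_from_pairs`; the default is the
    pure matching arithmetic.  Units left unmatched by a caliper
    (partner −1) are excluded from the average.
    """
    keep = pairs >= 0
    if not keep.any():
        raise PositivityError("caliper left no matched units")
    safe_pairs = np.where(keep, pairs, 0)  # dummy partner for dropped units
    diffs = _unit_effects(cs.T, cs.Y, safe_pairs, cs.X if bias_adjust else None)
    return float(diffs[keep].mean())


def _group_means(X, T, Y):
    """Within-group linear outcome predictions (mu0_hat, mu1_hat) at every X.

    Ordinary least squares of Y on [1, X] fit separately on controls and on
    treated units.  Returns None for a group too small or too collinear to
    fit, in which case the caller skips the correction for that group.
    """
    A = np.column_stack([np.ones(len(T)), X])
    out = []
    for g in (0, 1):
        rows = T == g
        Ag = A[rows]
        if Ag.shape[0] <= Ag.shape[1]:
            out.append(None)
            continue
        AtA = Ag.T @ Ag
        Aty = Ag.T @ Y[rows]
        try:
            coef = np.linalg.solve(AtA, Aty)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(Ag, Y[rows], rcond=None)[0]
        if not np.all(np.isfinite(coef)):
            out.append(None)
            continue
        out.append(A @ coef)
    return out


def _ate_from_pairs(T, Y, pairs, X=None) -> float:
    return float(_unit_effects(T, Y, pairs, X).mean())


def _unit_effects(T, Y, pairs, X=None) -> np.ndarray:
    """Per-unit imputed Y(1)−Y(0).

    Raw form (X is None): treated units impute Y(0) from the matched
    control's outcome and vice versa.  Bias-adjusted form (X given): the
    matched outcome is shifted by the within-group linear regression
    prediction difference mu_hat(X_i) − mu_hat(X_j), removing the
    first-order error from the covariate discrepancy between a unit and its
    match (the standard regression correction for nearest-neighbour
    matching).
    """
    y_match = Y[pairs]
    if X is None:
        return np.where(T == 1, Y - y_match, y_match - Y)
    mu0, mu1 = _group_means(X, T, Y)
    adj0 = mu0 - mu0[pairs] if mu0 is not None else 0.0
    adj1 = mu1 - mu1[pairs] if mu1 is not None else 0.0
    # treated: own Y minus corrected control imputation; control: corrected
    # treated imputation minus own Y
    return np.where(T == 1, Y - (y_match + adj0), (y_match + adj1) - Y)


def _ate_core(X: np.ndarray, T: np.ndarray, Y: np.ndarray,
              bias_adjust: bool = True) -> float:
    """Fit propensity, match, and return the matched ATE (hot path)."""
    scores = _propensity_scores(X, T)
    pairs = _nearest_opposite(scores, T.astype(int))
    return _ate_from_pairs(T, Y, pairs, X if bias_adjust else None)


class MatchResult:
    """Bundle of a full matching run: scores, pairs, ATE, group counts."""

    def __init__(self, cs: CrossSection, bias_adjust: bool = True):
        self.scores = fit_propensity(cs)
        self.pairs = match_units(self.scores, cs.T)
        self.ate = matched_ate(cs, self.pairs, bias_adjust=bias_adjust)
        self.n_treated = int(cs.T.sum())
        self.n_control = int(len(cs.T) - self.n_treated)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MatchResult(ate={self.ate:.4g}, "
                f"treated={self.n_treated}, control={self.n_control})")


def estimate_ate(cs: CrossSection, bias_adjust: bool = True) -> MatchResult:
    """Convenience one-call propensity-match ATE on a cross-section."""
    return MatchResult(cs, bias_adjust=bias_adjust)
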