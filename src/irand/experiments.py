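"""Monte-Carlo studies: estimator comparison surfaces, hidden-confounder
sensitivity, subsample-count scaling, and null calibration.

Every study derives per-replicate seeds from a master seed through
``numpy.random.SeedSequence`` spawned on (master, cell index, replicate
index), so any cell can be re-run independently and the whole study is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .benchmarks import did_bmi_like, did_stacked_lcd, pooled_ate
from .errors import DesignError
from .irand import irand_estimate, summarize_pvalues
from .matching import _ate_core
from .panel import TwoPointPanel
from .simulate import DGPConfig, gen_panel

__all__ = [
    "SurfaceResult",
    "run_grid",
    "hidden_confounder_study",
    "subsample_count_study",
    "null_calibration_study",
    "METHODS",
]


def _irand_method(panel: TwoPointPanel, seed: int, M: int = 500) -> float:
    return irand_estimate(panel, M=M, S=0, seed=seed).estimate


def _oracle_with_hidden(panel: TwoPointPanel, seed: int) -> float:
    """Pooled matched ATE that *does* adjust for the hidden confounder;
    available only on simulated panels that kept the z column."""
    cols = list(panel.meta.get("confounders", [])) + ["z"]
    T0, T1 = panel.column_pair("treatment")
    Y0, Y1 = panel.column_pair("outcome")
    X0, X1 = panel.arrays(cols)
    T = np.concatenate([T0, T1]).astype(float)
    Y = np.concatenate([Y0, Y1]).astype(float)
    X = np.vstack([X0, X1])
    return _ate_core(X, T, Y)


#: method registry: name -> callable(panel, seed) -> estimate
METHODS = {
    "irand": _irand_method,
    "pooled": lambda panel, seed: pooled_ate(panel),
    "did_stacked": lambda panel, seed: did_stacked_lcd(panel),
    "did_bmi": lambda panel, seed: did_bmi_like(panel),
    "oracle_hidden": _oracle_with_hidden,
}

_DESIGN_OK = {
    "did_stacked": {"lcd_like"},
    "did_bmi": {"bmi_like"},
}


@dataclass
class SurfaceResult:
    """MSE / bias^2 / variance grids per method over (n, sigma) cells."""

    n_values: list[int]
    sigma_values: list[float]
    methods: list[str]
    R: int
    seed: int | None
    delta: float
    #: estimates[method][i, j, r]: cell (n_values[i], sigma_values[j]), rep r
    estimates: dict[str, np.ndarray]

    def metric(self, method: str, which: str) -> np.ndarray:
        est = self.estimates[method]
        err = est - self.delta
        if which == "mse":
            return (err**2).mean(axis=2)
        if which == "bias2":
            return err.mean(axis=2) ** 2
        if which == "variance":
            return est.var(axis=2)  # population variance: mse = bias2 + var
        raise ValueError(f"unknown metric {which!r}")

    def mc_se_bias(self, method: str) -> np.ndarray:
        """Monte-Carlo standard error of the bias estimate per cell."""
        est = self.estimates[method]
        return est.std(axis=2, ddof=1) / np.sqrt(self.R)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method in self.methods:
            for which in ("mse", "bias2", "variance"):
                grid = self.metric(method, which)
                for i, n in enumerate(self.n_values):
                    for j, s in enumerate(self.sigma_values):
                        rows.append({"method": method, "metric": which,
                                     "n": n, "sigma": s, "value": grid[i, j],
                                     "R": self.R})
        return pd.DataFrame(rows)


def _replicate_seed(master: int | None, *idx: int) -> int:
    ss = np.random.SeedSequence([0 if master is None else int(master), *idx])
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(
    dgp: DGPConfig,
    methods: list[str],
    n_values: list[int],
    sigma_values: list[float],
    R: int = 100,
    seed: int | None = None,
    M: int = 500,
) -> SurfaceResult:
    """R replicates per (n, sigma) cell; records each method's estimate.

    ``dgp`` is the template config; per cell its ``n`` and ``sigma`` are
    replaced.  Raises :class:`DesignError` up front for method/design
    mismatches (e.g. the stacked-control DiD on a non-all-treated design).
    """
    if R < 2:
        raise ValueError("need R >= 2 replicates")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
        ok = _DESIGN_OK.get(m)
        if ok and dgp.treatment_design not in ok:
            raise DesignError(f"method {m!r} is not applicable to the "
                              f"{dgp.treatment_design!r} design")
    estimates = {m: np.empty((len(n_values), len(sigma_values), R)) for m in methods}
    for i, n in enumerate(n_values):
        for j, sig in enumerate(sigma_values):
            for r in range(R):
                s = _replicate_seed(seed, i, j, r)
                panel = gen_panel(dgp.replace(n=n, sigma=sig, seed=s))
                for m in methods:
                    fn = METHODS[m]
                    estimates[m][i, j, r] = (
                        fn(panel, s, M=M) if m == "irand" else fn(panel, s))
    return SurfaceResult(
        n_values=list(n_values), sigma_values=list(sigma_values),
        methods=list(methods), R=R, seed=seed, delta=dgp.delta,
        estimates=estimates)


def hidden_confounder_study(
    dgp: DGPConfig,
    n_values: list[int],
    sigma_values: list[float],
    R: int = 100,
    seed: int | None = None,
    M: int = 500,
) -> SurfaceResult:
    """Sensitivity study: hidden confounder generated but withheld from the
    estimators; an oracle that adjusts for it is recorded alongside."""
    if not dgp.hidden_confounder:
        raise ValueError("config must set hidden_confounder=True")
    return run_grid(dgp, ["irand", "pooled", "oracle_hidden"],
                    n_values, sigma_values, R=R, seed=seed, M=M)


def subsample_count_study(
    dgp: DGPConfig,
    M_values: list[int],
    R: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """MSE / bias^2 / variance of the I-Rand estimate as M grows.

    One panel is drawn and held fixed; each of the R replicates reruns the
    estimator with fresh subsample randomness.  The reported variance is
    therefore the subsample-randomization variance of the estimator on that
    dataset — the quantity that shrinks as more subsamples are averaged —
    and bias^2 is the panel-conditional squared bias.
    """
    panel = gen_panel(dgp.replace(seed=_replicate_seed(seed, 0)))
    rows = []
    for mi, M in enumerate(M_values):
        est = np.empty(R)
        for r in range(R):
            s = _replicate_seed(seed, 1 + mi, r)
            est[r] = irand_estimate(panel, M=M, S=0, seed=s).estimate
        err = est - dgp.delta
        rows.append({"M": M, "mse": float((err**2).mean()),
                     "bias2": float(err.mean() ** 2),
                     "variance": float(est.var()), "R": R})
    return pd.DataFrame(rows)


def null_calibration_study(
    dgp: DGPConfig,
    R: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    M: int = 20,
    S: int = 200,
) -> dict:
    """Type-I-error calibration under the no-effect null (delta = 0).

    Per replicate: draw a panel, run I-Rand with permutation inference, and
    record the median subsample p-value.  Reports the rejection rate at
    ``alpha`` (median-p rule) and the Kolmogorov–Smirnov distance of the
    pooled p-values from U(0,1).
    """
    if dgp.delta != 0 and alpha < 1:
        # the study is about the null; a nonzero delta turns it into a
        # power study, which is also useful — the caller decides
        pass
    medians = np.empty(R)
    pooled = []
    for r in range(R):
        s = _replicate_seed(seed, r)
        panel = gen_panel(dgp.replace(seed=s))
        res = irand_estimate(panel, M=M, S=S, seed=s)
        medians[r] = summarize_pvalues(res, alpha)["median"]
        pooled.append(res.pvalues)
    pooled = np.concatenate(pooled)
    ks = stats.kstest(pooled, "uniform").statistic
    return {
        "rejection_rate": float(np.mean(medians < alpha)),
        "alpha": alpha,
        "ks_uniform": float(ks),
        "median_pvalues": medians,
        "pooled_pvalues": pooled,
        "R": R, "M": M, "S": S,
    }
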