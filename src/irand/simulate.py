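"""Synthetic two-visit panel generators.

Two families of data are produced here:

* :func:`gen_panel` draws from the structural model used throughout the
  simulation studies,

  .. math:: Y_{i,t} = \\alpha + \\delta T_{i,t} + X_{i,t}\\beta
            \\ [+ Z_{i,t}\\gamma] + \\varepsilon^Y_{i,t},

  with a continuous age-like confounder that carries a between-visit time
  trend and a binary confounder held fixed across visits.  Treatment is
  either determined by the visit (``lcd_like``: everyone untreated at
  baseline, treated at follow-up — the design of a dietary-intervention
  clinic with no control group) or drawn per visit from a noisy logistic
  function of the confounders (``bmi_like``), optionally confounded by a
  hidden binary variable Z.

* :func:`gen_nutrition_like` emulates the *structure* of a primary-care
  nutrition study: gender, age, a BMI mediator that responds to the diet,
  a 3-level ordinal type-2-diabetes outcome obtained by thresholding a
  latent HbA1c-like score, and a continuous cardiovascular-risk outcome
  with both direct and BMI/T2D-mediated treatment paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import IRandError
from .panel import TwoPointPanel

__all__ = ["DGPConfig", "gen_panel", "gen_nutrition_like", "NUTRITION_DEFAULTS"]


@dataclass
class DGPConfig:
    """Configuration of the simulation data-generating process.

    Attributes
    ----------
    n : number of individuals.
    sigma : outcome noise SD (>= 0).
    rho : between-visit correlation of the age-like confounder, |rho| <= 1.
    mu, age_sd : mean and SD of baseline age.
    alpha : outcome intercept.
    delta : true treatment effect on the outcome.
    beta : outcome coefficients on (age, group).
    beta_T : treatment-assignment coefficients on (age, group); bmi_like only.
    gamma, gamma_T : hidden-confounder coefficients on outcome / assignment.
    p_hidden : Bernoulli probability of the hidden confounder.
    treatment_design : 'lcd_like' (T = visit indicator) or 'bmi_like'
        (noisy-logistic assignment at each visit).
    hidden_confounder : include the unobserved Z in the generating equations.
    visit_gap_max : the between-visit gap is Unif{1..visit_gap_max} months.
    seed : RNG seed; identical config+seed reproduces the panel bit-for-bit.
    """

    n: int = 500
    sigma: float = 1.0
    rho: float = 0.9
    mu: float = 40.0
    age_sd: float = 10.0
    alpha: float = 0.0
    delta: float = 1.0
    beta: tuple[float, float] = (1.0, 1.0)
    beta_T: tuple[float, float] = (1.0 / 40.0, -1.0)
    gamma: float = 1.0
    gamma_T: float = -0.5
    p_hidden: float = 0.5
    treatment_design: str = "lcd_like"
    hidden_confounder: bool = False
    visit_gap_max: int = 24
    seed: int | None = None

    #: confounder dimension implied by the generating equations
    K: int = field(default=2, init=False, repr=False)

    def validate(self) -> None:
        if self.n < 2:
            raise IRandError("need at least n=2 individuals")
        if self.sigma < 0:
            raise IRandError("sigma must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise IRandError("|rho| must be <= 1")
        if not 0.0 <= self.p_hidden <= 1.0:
            raise IRandError("p_hidden must be in [0, 1]")
        if self.age_sd <= 0:
            raise IRandError("age_sd must be positive")
        if len(self.beta) != self.K or len(self.beta_T) != self.K:
            raise IRandError(
                f"beta and beta_T must have length {self.K} (age, group)"
            )
        if self.treatment_design not in ("lcd_like", "bmi_like"):
            raise IRandError(f"unknown treatment_design {self.treatment_design!r}")
        if self.visit_gap_max < 1:
            raise IRandError("visit_gap_max must be >= 1")

    def replace(self, **kw) -> "DGPConfig":
        d = asdict(self)
        d.pop("K", None)
        d.update(kw)
        return DGPConfig(**d)


def gen_panel(config: DGPConfig) -> TwoPointPanel:
    """Draw one two-visit panel from the configured generating process.

    Returns a :class:`TwoPointPanel` with columns ``treatment``, ``outcome``,
    ``age``, ``group``, ``gap`` and — when a hidden confounder is simulated —
    ``z`` (kept for oracle checks only; estimators must not use it).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    beta = np.asarray(config.beta, dtype=float)

    # baseline confounders
    age0 = config.mu + config.age_sd * rng.standard_normal(n)
    group = rng.integers(0, 2, n).astype(float)  # Unif{0,1}, visit-constant
    # follow-up: time trend on age, gap measured in months
    gap = rng.integers(1, config.visit_gap_max + 1, n)
    age1 = gap + config.rho * age0 + np.sqrt(1.0 - config.rho**2) * rng.standard_normal(n)

    X0 = np.column_stack([age0, group])
    X1 = np.column_stack([age1, group])

    if config.hidden_confounder:
        z0 = (rng.random(n) < config.p_hidden).astype(float)
        z1 = (rng.random(n) < config.p_hidden).astype(float)  # redrawn per visit
    else:
        z0 = z1 = np.zeros(n)

    if config.treatment_design == "lcd_like":
        t0 = np.zeros(n, dtype=int)
        t1 = np.ones(n, dtype=int)
    else:
        t0 = _noisy_logistic_treatment(X0, z0, config, rng)
        t1 = _noisy_logistic_treatment(X1, z1, config, rng)

    def outcome(X, z, t):
        eps = config.sigma * rng.standard_normal(n)
        return config.alpha + config.delta * t + X @ beta + config.gamma * z + eps

    y0 = outcome(X0, z0, t0)
    y1 = outcome(X1, z1, t1)

    rows = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n), 2),
            "visit": np.tile([0, 1], n),
            "treatment": np.column_stack([t0, t1]).ravel(),
            "outcome": np.column_stack([y0, y1]).ravel(),
            "age": np.column_stack([age0, age1]).ravel(),
            "group": np.repeat(group, 2),
            "gap": np.repeat(gap, 2),
        }
    )
    if config.hidden_confounder:
        rows["z"] = np.column_stack([z0, z1]).ravel()
    meta = asdict(config)
    meta.pop("K", None)
    meta["confounders"] = ["age", "group"]
    return TwoPointPanel(rows, meta=meta)


def _noisy_logistic_treatment(X, z, config, rng):
    """T ~ Bernoulli(p), p = (1 + exp(X beta_T + Z gamma_T + eps))^-1.

    The latent N(0,1) noise sits *inside* the link, and the link is a
    decreasing function of the linear index — both as the generating
    equations define them.
    """
    beta_T = np.asarray(config.beta_T, dtype=float)
    eta = X @ beta_T + rng.standard_normal(len(z))
    if config.hidden_confounder:
        eta = eta + config.gamma_T * z
    p = 1.0 / (1.0 + np.exp(eta))
    return (rng.random(len(z)) < p).astype(int)


# ---------------------------------------------------------------------------
# nutrition-study-like generator

#: default path coefficients of the nutrition-like generator; every entry can
#: be overridden through gen_nutrition_like(..., coefficients={...}).
NUTRITION_DEFAULTS: dict[str, float] = {
    # demographics
    "age_mean": 55.0,
    "age_sd": 12.0,
    "age_rho": 0.95,
    # BMI mediator model: bmi = b0 + b_age*age + b_gender*gender + a_lcd*T + noise
    "bmi_b0": 24.0,
    "bmi_b_age": 0.08,
    "bmi_b_gender": 1.0,
    "bmi_a_lcd": -2.0,  # diet lowers BMI
    "bmi_sd": 3.5,
    # latent HbA1c-like score: h = h0 + c_bmi*bmi + c_lcd*T + c_age*age + noise
    "h_0": 20.0,
    "h_c_bmi": 0.6,
    "h_c_lcd": -3.0,
    "h_c_age": 0.05,
    "h_sd": 2.0,
    # ordinal T2D thresholds on the latent score (non- / pre- / diabetic)
    "t2d_cut1": 39.0,
    "t2d_cut2": 42.0,
    # CVD risk score: cvd = d0 + d_lcd*T + d_bmi*bmi + d_age*age
    #                      + d_gender*gender + noise
    "cvd_d0": 5.0,
    "cvd_d_lcd": -1.0,
    "cvd_d_bmi": 0.4,
    "cvd_d_age": 0.1,
    "cvd_d_gender": 0.5,
    "cvd_sd": 1.5,
}


def gen_nutrition_like(
    n: int, seed: int | None = None, coefficients: dict[str, float] | None = None
) -> TwoPointPanel:
    """Generate a panel shaped like a two-visit dietary-intervention study.

    All individuals start an LCD (low-carbohydrate diet) after the baseline
    visit, so ``treatment`` equals the visit indicator.  Columns: ``gender``
    (binary), ``age`` (continuous, with between-visit trend), ``bmi``
    (continuous mediator, lowered by the diet), ``t2d`` (ordinal 0/1/2 from a
    thresholded latent HbA1c-like variable), ``cvd_risk`` (continuous, with
    direct and BMI-mediated diet paths), ``outcome`` (alias of ``t2d``).

    The generating coefficients are returned in ``panel.meta['params']``
    together with the implied total diet->T2D-latent path, so tests can
    check recovered effects against the configured truth.
    """
    if n < 2:
        raise IRandError("need at least n=2 individuals")
    p = dict(NUTRITION_DEFAULTS)
    if coefficients:
        unknown = set(coefficients) - set(p)
        if unknown:
            raise IRandError(f"unknown nutrition coefficients {sorted(unknown)}")
        p.update(coefficients)
    rng = np.random.default_rng(seed)

    gender = rng.integers(0, 2, n).astype(float)
    age0 = p["age_mean"] + p["age_sd"] * rng.standard_normal(n)
    gap = rng.integers(1, 25, n)
    age1 = gap / 12.0 + p["age_rho"] * age0 + np.sqrt(
        1 - p["age_rho"] ** 2
    ) * rng.standard_normal(n)

    t0 = np.zeros(n)
    t1 = np.ones(n)

    def bmi(age, t):
        return (
            p["bmi_b0"]
            + p["bmi_b_age"] * age
            + p["bmi_b_gender"] * gender
            + p["bmi_a_lcd"] * t
            + p["bmi_sd"] * rng.standard_normal(n)
        )

    bmi0, bmi1 = bmi(age0, t0), bmi(age1, t1)

    def latent_h(age, b, t):
        return (
            p["h_0"]
            + p["h_c_bmi"] * b
            + p["h_c_lcd"] * t
            + p["h_c_age"] * age
            + p["h_sd"] * rng.standard_normal(n)
        )

    h0, h1 = latent_h(age0, bmi0, t0), latent_h(age1, bmi1, t1)
    t2d0 = np.digitize(h0, [p["t2d_cut1"], p["t2d_cut2"]])
    t2d1 = np.digitize(h1, [p["t2d_cut1"], p["t2d_cut2"]])

    def cvd(age, b, t):
        return (
            p["cvd_d0"]
            + p["cvd_d_lcd"] * t
            + p["cvd_d_bmi"] * b
            + p["cvd_d_age"] * age
            + p["cvd_d_gender"] * gender
            + p["cvd_sd"] * rng.standard_normal(n)
        )

    cvd0, cvd1 = cvd(age0, bmi0, t0), cvd(age1, bmi1, t1)

    rows = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n), 2),
            "visit": np.tile([0, 1], n),
            "treatment": np.column_stack([t0, t1]).ravel().astype(int),
            "outcome": np.column_stack([t2d0, t2d1]).ravel(),
            "t2d": np.column_stack([t2d0, t2d1]).ravel(),
            "cvd_risk": np.column_stack([cvd0, cvd1]).ravel(),
            "bmi": np.column_stack([bmi0, bmi1]).ravel(),
            "age": np.column_stack([age0, age1]).ravel(),
            "gender": np.repeat(gender, 2),
            "gap": np.repeat(gap, 2),
        }
    )
    meta = {
        "design": "nutrition_like",
        "n": n,
        "seed": seed,
        "params": p,
        # total diet effect on the latent HbA1c scale: direct + via BMI
        "latent_total_lcd_path": p["h_c_lcd"] + p["bmi_a_lcd"] * p["h_c_bmi"],
        # total diet effect on CVD risk: direct + via BMI
        "cvd_total_lcd_path": p["cvd_d_lcd"] + p["bmi_a_lcd"] * p["cvd_d_bmi"],
        "confounders": ["age", "gender"],
    }
    return TwoPointPanel(rows, meta=meta)
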