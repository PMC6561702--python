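"""Probabilistic model of repeated landing attempts.

For a fixed situation (ledge class, species, height band, turbulence
level) the statistical model collapses to a logistic curve in wind
speed alone,

    p(W) = a / (a + exp(b W)),          a > 0,

with success declining in wind when b > 0.  A bird attempting to land
repeatedly samples the instantaneous cliff wind anew on each approach;
that wind is modelled as LogNormal(m, s²) with m, s chosen so the draw
has mean U (mean cliff wind) and SD u (root-mean-square turbulent
fluctuation, u = TI x U).  The number of attempts S to the first
success is then geometric with parameter

    P = E[p(W)] = ∫ p(W) LogNormal(W; m, s²) dW,

evaluated by quadrature on the standardised log scale (a Monte-Carlo
oracle is provided for cross-checking).  Finally, mean at-sea winds
translate to cliff winds through a scaling constant from the airflow
modelling, giving landing-probability curves against open-water wind
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from cliffwind.glmm import GlmmFit, predict_success, _profile_eta
from cliffwind.windfield import ScalingConstant


@dataclass(frozen=True)
class LogisticLanding:
    """Logistic landing-success curve p(W) = a / (a + e^{bW})."""

    a: float
    b: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("a must be > 0")

    def __call__(self, W):
        return landing_prob_given_wind(self, W)


@dataclass(frozen=True)
class WindDistribution:
    """LogNormal instantaneous cliff wind with moments (U, u).

    m and s are the log-scale location and scale; e^{m+s²/2} = U and
    (e^{s²}-1) e^{2m+s²} = u².  s = 0 is the degenerate point mass at U.
    """

    U: float
    u: float
    m: float
    s: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.s == 0.0:
            return np.full(n, self.U)
        return rng.lognormal(self.m, self.s, size=n)


@dataclass(frozen=True)
class AttemptDistribution:
    """Geometric law of the number of attempts S to the first success.

    P(S = n) = (1-P)^{n-1} P for n = 1, 2, ...; E[S] = 1/P.
    """

    P: float

    def __post_init__(self):
        if not 0.0 < self.P <= 1.0:
            raise ValueError("success probability P must lie in (0, 1]")

    @property
    def expected_attempts(self) -> float:
        return 1.0 / self.P

    def pmf(self, n):
        n = np.asarray(n)
        out = np.where(n >= 1, (1.0 - self.P) ** (np.maximum(n, 1) - 1) * self.P, 0.0)
        return float(out) if out.ndim == 0 else out

    def cumulative(self, n):
        """P(S <= n): probability of having landed within n attempts."""
        n = np.asarray(n)
        out = np.where(n >= 1, 1.0 - (1.0 - self.P) ** np.maximum(n, 0), 0.0)
        return float(out) if out.ndim == 0 else out

    def quantile(self, q: float) -> int:
        """Smallest n with P(S <= n) >= q."""
        if not 0.0 < q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.P == 1.0:
            return 1
        return int(math.ceil(math.log1p(-q) / math.log1p(-self.P)))


def landing_prob_given_wind(model: LogisticLanding, W):
    """p(W) = a / (a + e^{bW}), the per-attempt success probability.

    Strictly decreasing in W when b > 0; p(0) = a/(a+1).  Evaluated
    stably for large bW via the log-sum-exp form.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("wind speed W must be >= 0")
    # a/(a + e^{bW}) = expit(ln a - bW)
    from scipy.special import expit

    p = expit(math.log(model.a) - model.b * W)
    return float(p) if p.ndim == 0 else p


def logistic_from_glmm(fit: GlmmFit, profile) -> LogisticLanding:
    """Collapse a fitted model to the (a, b) logistic form for a profile.

    With total wind slope beta_w (main effect plus the wind x ledge
    offset for the profile's ledge) and eta0 the linear predictor the
    fit assigns at raw wind W = 0, the identity p(W) = expit(eta0 +
    beta_w W) = a/(a + e^{bW}) holds with b = -beta_w and a = e^{eta0}.
    The turbulence covariate is held at the profile's value (default:
    its centring mean).  Exact: agrees with ``predict_success`` at
    every W.
    """
    eta0 = float(_profile_eta(fit, profile, 0.0))
    eta1 = float(_profile_eta(fit, profile, 1.0))
    beta_w = eta1 - eta0  # total wind slope for this profile
    return LogisticLanding(a=math.exp(eta0), b=-beta_w)


def lognormal_from_moments(U: float, u: float) -> WindDistribution:
    """LogNormal(m, s²) matching mean U and SD u.

    s² = ln(1 + u²/U²), m = ln U - s²/2; u = 0 gives the degenerate
    s = 0, m = ln U.
    """
    if U <= 0:
        raise ValueError("mean wind U must be > 0")
    if u < 0:
        raise ValueError("fluctuation SD u must be >= 0")
    s2 = math.log1p((u / U) ** 2)
    m = math.log(U) - s2 / 2.0
    return WindDistribution(U=float(U), u=float(u), m=m, s=math.sqrt(s2))


def mean_landing_prob(
    model: LogisticLanding, wind: WindDistribution, epsabs: float = 1e-10
) -> float:
    """P = E[p(W)] under the LogNormal wind, by adaptive quadrature.

    Integrates on the standardised log-wind variable t = (ln W - m)/s
    over ±10 s, where the integrand is p(e^{m+st}) phi(t): smooth,
    bounded by the Normal density, with tail truncation error below the
    Normal tail mass at 10 SD (~1e-23).  Raises ``RuntimeError`` if the
    quadrature reports non-convergence.
    """
    if wind.s == 0.0:
        return float(landing_prob_given_wind(model, wind.U))

    def integrand(t):
        W = np.exp(wind.m + wind.s * t)
        return landing_prob_given_wind(model, W) * stats.norm.pdf(t)

    P, err, info, *rest = integrate.quad(
        integrand, -10.0, 10.0, epsabs=epsabs, limit=200, full_output=True)
    if rest:
        raise RuntimeError(f"quadrature did not converge: {rest[0]}")
    if err > 1e-6:
        raise RuntimeError(f"quadrature error estimate too large: {err:g}")
    return float(min(max(P, 0.0), 1.0))


def mean_landing_prob_mc(
    model: LogisticLanding, wind: WindDistribution, n_draws: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo oracle for E[p(W)]: (estimate, standard error).

    Averages p over ``n_draws`` LogNormal winds; SE is the sample SD
    over sqrt(n_draws).  Deterministic under ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    W = wind.sample(int(n_draws), rng)
    p = landing_prob_given_wind(model, W)
    est = float(np.mean(p))
    se = float(np.std(p, ddof=1) / math.sqrt(n_draws)) if n_draws > 1 else 0.0
    return est, se


def attempt_distribution(P: float) -> AttemptDistribution:
    """Geometric attempt distribution with per-attempt success P."""
    return AttemptDistribution(P=float(P))


def landing_curve_at_sea(
    model: LogisticLanding,
    TI: float,
    scaling: ScalingConstant,
    sea_winds,
    max_attempts: int = 20,
) -> pd.DataFrame:
    """Landing curves against mean at-sea wind speed.

    For each open-water wind w: cliff mean U = ratio * w, fluctuation
    u = TI * U, then the LogNormal mixing integral gives the
    per-attempt success P and the geometric law gives the cumulative
    probability of having landed within 1..max_attempts attempts.

    Returns a table with columns ``sea_wind, cliff_wind, P,
    expected_attempts, cum_1 .. cum_<max_attempts>``.  TI defaults in
    the published curves to 0.2.
    """
    if TI < 0:
        raise ValueError("turbulence intensity must be >= 0")
    rows = []
    for w in np.asarray(sea_winds, dtype=float):
        if w < 0:
            raise ValueError("sea wind speeds must be >= 0")
        U = scaling.ratio * w
        if U == 0.0:
            P = float(landing_prob_given_wind(model, 0.0))
        else:
            P = mean_landing_prob(model, lognormal_from_moments(U, TI * U))
        att = AttemptDistribution(P=P)
        row = {"sea_wind": float(w), "cliff_wind": float(U), "P": P,
               "expected_attempts": att.expected_attempts}
        for n in range(1, max_attempts + 1):
            row[f"cum_{n}"] = float(att.cumulative(n))
        rows.append(row)
    return pd.DataFrame(rows)
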