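"""Posterior probability of treatment superiority for the two-arm normal model.

Model (shared residual variance, independent arm-mean priors):

    y_di | theta_d, sigma^2  ~  N(theta_d, sigma^2)        d = control, treatment
    theta_d                  ~  N(mu_d, v_d^2)
    sigma^2                  ~  Scaled-inv-chi2(w, s^2)

The quantity monitored at every analysis is Pr(theta_t > theta_c | data). Given
sigma^2 the model is conjugate: each theta_d posterior is normal with precision
1/v_d^2 + n_d/sigma^2, so

    Pr(theta_t > theta_c | data, sigma^2) = Phi( (m_t - m_c) / sqrt(s_t^2 + s_c^2) )

and the marginal probability is a one-dimensional integral of that quantity
against p(sigma^2 | data), which is available in closed form up to normalization.

Three estimators are provided:

``sigma_marginal_quadrature`` (default)
    Deterministic trapezoid quadrature of the closed-form integrand over a
    per-dataset log-spaced sigma^2 grid. Exact to quadrature error (~1e-6),
    independent of batch composition, and fast when vectorized across many
    interim datasets at once.
``gibbs_rao_blackwell``
    Gibbs sampler alternating theta | sigma^2 and sigma^2 | theta, returning the
    Rao-Blackwellized average of the normal-CDF term over sigma^2 draws. Serves
    as a sampling-based cross-check of the quadrature path.
``known_variance_plugin``
    Closed form with sigma^2 fixed at the pooled sample variance.

Only sufficient statistics per arm (n, mean, sum of squared deviations) are
required; raw responses are reducible without loss under the normal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special, stats

from .priors import PriorCommunity, VariancePrior

__all__ = [
    "ArmSummary",
    "PosteriorSettings",
    "InsufficientDataError",
    "prob_superiority",
    "prob_superiority_known_variance",
    "one_sided_p_value",
    "prob_superiority_arrays",
    "p_value_arrays",
]

_SQRT2 = np.sqrt(2.0)


def _ndtr(x):
    return special.ndtr(x)


class InsufficientDataError(ValueError):
    """Raised when an analysis is requested with fewer than two outcomes per arm."""


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics for one arm: count, sample mean, and within-arm SSE."""

    n: int
    mean: float
    sse: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be nonnegative, got {self.n}")
        if self.sse < 0:
            raise ValueError(f"sse must be nonnegative, got {self.sse}")
        if self.n == 0 and self.sse != 0:
            raise ValueError("an empty arm must have sse = 0")

    @classmethod
    def from_samples(cls, y) -> "ArmSummary":
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            return cls(0, float("nan"), 0.0)
        m = float(y.mean())
        return cls(int(y.size), m, float(((y - m) ** 2).sum()))


@dataclass(frozen=True)
class PosteriorSettings:
    """Numerical settings for the posterior-probability estimator.

    ``draws`` is the total chain length for the Gibbs path; averaging starts
    after ``burn_in`` iterations (defaults 4500/500, i.e. 4000 retained draws).
    ``grid_size`` controls the quadrature resolution.
    """

    draws: int = 4500
    burn_in: int = 500
    seed: int = 0
    estimator: str = "sigma_marginal_quadrature"
    grid_size: int = 160

    def __post_init__(self) -> None:
        if not self.draws > self.burn_in >= 0:
            raise ValueError("require draws > burn_in >= 0")
        if self.estimator not in (
            "sigma_marginal_quadrature",
            "gibbs_rao_blackwell",
            "known_variance_plugin",
        ):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.grid_size < 16:
            raise ValueError("grid_size must be at least 16")


def _as_arrays(control: ArmSummary, treatment: ArmSummary):
    return (
        np.array([control.n], dtype=float),
        np.array([control.mean], dtype=float),
        np.array([control.sse], dtype=float),
        np.array([treatment.n], dtype=float),
        np.array([treatment.mean], dtype=float),
        np.array([treatment.sse], dtype=float),
    )


def prob_superiority(
    control: ArmSummary,
    treatment: ArmSummary,
    community: PriorCommunity,
    vprior: VariancePrior,
    settings: Optional[PosteriorSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Pr(theta_treatment > theta_control | data) under one prior community.

    Requires at least two observed outcomes per arm so the residual variance is
    identified; otherwise raises :class:`InsufficientDataError`, which interim
    monitoring treats as a no-decision look.
    """
    if control.n < 2 or treatment.n < 2:
        raise InsufficientDataError(
            f"need >= 2 observed outcomes per arm, got control n={control.n}, "
            f"treatment n={treatment.n}"
        )
    settings = settings or PosteriorSettings()
    arrays = _as_arrays(control, treatment)
    if settings.estimator == "known_variance_plugin":
        df = control.n + treatment.n - 2
        sigma = float(np.sqrt((control.sse + treatment.sse) / df)) if df > 0 else vprior.scale
        if sigma <= 0:
            sigma = vprior.scale
        return prob_superiority_known_variance(control, treatment, community, sigma)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    return float(
        prob_superiority_arrays(*arrays, community, vprior, settings, rng=rng)[0]
    )


def prob_superiority_known_variance(
    control: ArmSummary,
    treatment: ArmSummary,
    community: PriorCommunity,
    sigma: float,
) -> float:
    """Closed-form Pr(theta_t > theta_c | data) with known residual SD.

    Each arm posterior is conjugate normal; arms with n = 0 fall back to their
    prior, so the call with empty arms returns the prior probability of
    superiority, e.g. Phi(2) for the enthusiastic community.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    means, variances = [], []
    for arm_sum, arm_prior in (
        (control, community.control),
        (treatment, community.treatment),
    ):
        prior_prec = 1.0 / arm_prior.sd**2
        data_prec = arm_sum.n / sigma**2
        prec = prior_prec + data_prec
        num = arm_prior.mean * prior_prec
        if arm_sum.n > 0:
            num += arm_sum.n * arm_sum.mean / sigma**2
        means.append(num / prec)
        variances.append(1.0 / prec)
    z = (means[1] - means[0]) / np.sqrt(variances[0] + variances[1])
    return float(_ndtr(z))


def one_sided_p_value(control: ArmSummary, treatment: ArmSummary) -> float:
    """Pooled-variance one-sided two-sample t-test p-value for H1: treatment > control."""
    if control.n < 2 or treatment.n < 2:
        raise InsufficientDataError(
            f"t-test needs n >= 2 per arm, got {control.n} and {treatment.n}"
        )
    if control.sse + treatment.sse <= 0:
        raise ValueError("degenerate data: zero pooled variance")
    p = p_value_arrays(*_as_arrays(control, treatment))[0]
    return float(p)


def p_value_arrays(n_c, m_c, sse_c, n_t, m_t, sse_t) -> np.ndarray:
    """Vectorized pooled one-sided t-test p-values (H1: treatment > control).

    Entries with fewer than two outcomes in either arm, or zero pooled variance,
    return NaN.
    """
    n_c, m_c, sse_c, n_t, m_t, sse_t = map(np.asarray, (n_c, m_c, sse_c, n_t, m_t, sse_t))
    df = n_c + n_t - 2.0
    valid = (n_c >= 2) & (n_t >= 2) & (sse_c + sse_t > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (sse_c + sse_t) / np.where(df > 0, df, np.nan)
        se = np.sqrt(sp2 * (1.0 / n_c + 1.0 / n_t))
        tstat = (m_t - m_c) / se
    out = np.full(np.broadcast(n_c, n_t).shape, np.nan, dtype=float)
    if np.any(valid):
        out[valid] = stats.t.sf(tstat[valid], df[valid])
    return out


def prob_superiority_arrays(
    n_c,
    m_c,
    sse_c,
    n_t,
    m_t,
    sse_t,
    community: PriorCommunity,
    vprior: VariancePrior,
    settings: Optional[PosteriorSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Vectorized Pr(theta_t > theta_c | data) across many interim datasets.

    Inputs are parallel arrays of per-arm sufficient statistics; entries with
    fewer than two outcomes in either arm return NaN.
    """
    settings = settings or PosteriorSettings()
    n_c, m_c, sse_c, n_t, m_t, sse_t = (
        np.atleast_1d(np.asarray(a, dtype=float))
        for a in (n_c, m_c, sse_c, n_t, m_t, sse_t)
    )
    valid = (n_c >= 2) & (n_t >= 2)
    out = np.full(n_c.shape, np.nan, dtype=float)
    if not np.any(valid):
        return out
    args = (n_c[valid], m_c[valid], sse_c[valid], n_t[valid], m_t[valid], sse_t[valid])
    if settings.estimator == "gibbs_rao_blackwell":
        if rng is None:
            rng = np.random.default_rng(settings.seed)
        out[valid] = _gibbs_rb(*args, community, vprior, settings, rng)
    elif settings.estimator == "known_variance_plugin":
        df = args[0] + args[3] - 2.0
        sigma2 = (args[2] + args[5]) / df
        out[valid] = _conditional_prob(*args, community, sigma2)
    else:
        out[valid] = _quadrature(*args, community, vprior, settings.grid_size)
    return out


def _conditional_posterior(n, m, prior_mean, prior_sd, sigma2):
    """Conjugate posterior (mean, variance) of an arm mean given sigma^2."""
    prior_prec = 1.0 / prior_sd**2
    prec = prior_prec + n / sigma2
    mean = (prior_mean * prior_prec + n * m / sigma2) / prec
    return mean, 1.0 / prec


def _conditional_prob(n_c, m_c, sse_c, n_t, m_t, sse_t, community, sigma2):
    mc, vc = _conditional_posterior(
        n_c, m_c, community.control.mean, community.control.sd, sigma2
    )
    mt, vt = _conditional_posterior(
        n_t, m_t, community.treatment.mean, community.treatment.sd, sigma2
    )
    return _ndtr((mt - mc) / np.sqrt(vc + vt))


def _log_sigma2_posterior(sigma2, n_c, m_c, sse_c, n_t, m_t, sse_t, community, vprior):
    """Unnormalized log p(sigma^2 | data), theta integrated out analytically.

    Per arm: y-bar | sigma^2 ~ N(mu_d, v_d^2 + sigma^2/n_d) marginally, and the
    within-arm deviations contribute sigma^(-(n-1)) exp(-sse / 2 sigma^2).
    """
    w, s2 = vprior.weight, vprior.scale**2
    lp = -(0.5 * w + 1.0) * np.log(sigma2) - 0.5 * w * s2 / sigma2
    for n, m, sse, prior in (
        (n_c, m_c, sse_c, community.control),
        (n_t, m_t, sse_t, community.treatment),
    ):
        marg_var = prior.sd**2 + sigma2 / n
        lp = lp - 0.5 * (n - 1.0) * np.log(sigma2) - 0.5 * sse / sigma2
        lp = lp - 0.5 * np.log(marg_var) - 0.5 * (m - prior.mean) ** 2 / marg_var
    return lp


def _quadrature(n_c, m_c, sse_c, n_t, m_t, sse_t, community, vprior, grid_size):
    """Trapezoid quadrature over log sigma^2 of the closed-form integrand."""
    w, s2 = vprior.weight, vprior.scale**2
    n_tot = n_c + n_t
    a_post = 0.5 * (w + n_tot)
    # Bracket the sigma^2 posterior with inverse-gamma quantiles conditioned on
    # theta at the sample means (lower SS) and at the prior means (upper SS),
    # then widen; the marginal posterior mass lies between these extremes.
    ss_lo = w * s2 + sse_c + sse_t
    ss_hi = ss_lo + n_c * (m_c - community.control.mean) ** 2 + n_t * (
        m_t - community.treatment.mean
    ) ** 2
    lo = 0.25 * stats.invgamma.ppf(1e-11, a_post, scale=0.5 * ss_lo)
    hi = 4.0 * stats.invgamma.isf(1e-11, a_post, scale=0.5 * ss_hi)
    u = np.linspace(0.0, 1.0, grid_size)  # (G,)
    log_lo, log_hi = np.log(lo), np.log(hi)
    # (T, G) grid of sigma^2, log-spaced per dataset
    log_s2 = log_lo[:, None] + (log_hi - log_lo)[:, None] * u[None, :]
    sigma2 = np.exp(log_s2)
    lp = _log_sigma2_posterior(
        sigma2,
        n_c[:, None],
        m_c[:, None],
        sse_c[:, None],
        n_t[:, None],
        m_t[:, None],
        sse_t[:, None],
        community,
        vprior,
    )
    # integrate in u = log sigma^2: weight density by the Jacobian sigma^2
    lp = lp + log_s2
    lp -= lp.max(axis=1, keepdims=True)
    wgt = np.exp(lp)
    wgt[:, 0] *= 0.5
    wgt[:, -1] *= 0.5
    wgt /= wgt.sum(axis=1, keepdims=True)
    prob = _conditional_prob(
        n_c[:, None],
        m_c[:, None],
        sse_c[:, None],
        n_t[:, None],
        m_t[:, None],
        sse_t[:, None],
        community,
        sigma2,
    )
    return (wgt * prob).sum(axis=1)


def _gibbs_rb(n_c, m_c, sse_c, n_t, m_t, sse_t, community, vprior, settings, rng):
    """Rao-Blackwellized Gibbs: average the normal-CDF term over sigma^2 draws."""
    w, s2 = vprior.weight, vprior.scale**2
    size = n_c.shape
    df_post = w + n_c + n_t
    # initialize sigma^2 at the prior-data pooled point estimate
    sigma2 = (w * s2 + sse_c + sse_t) / df_post
    acc = np.zeros(size)
    kept = 0
    for it in range(settings.draws):
        mc, vc = _conditional_posterior(
            n_c, m_c, community.control.mean, community.control.sd, sigma2
        )
        mt, vt = _conditional_posterior(
            n_t, m_t, community.treatment.mean, community.treatment.sd, sigma2
        )
        if it >= settings.burn_in:
            acc += _ndtr((mt - mc) / np.sqrt(vc + vt))
            kept += 1
        theta_c = mc + np.sqrt(vc) * rng.standard_normal(size)
        theta_t = mt + np.sqrt(vt) * rng.standard_normal(size)
        ss = (
            w * s2
            + sse_c
            + n_c * (m_c - theta_c) ** 2
            + sse_t
            + n_t * (m_t - theta_t) ** 2
        )
        sigma2 = ss / rng.chisquare(df_post, size=size)
    return acc / kept
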