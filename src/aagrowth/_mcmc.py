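"""Metropolis-within-Gibbs samplers for the hierarchical growth models.

Both models share the structure: per-patient parameters drawn from a
population (partial pooling), Gaussian measurement noise on the cm scale,
weakly informative hyperpriors. Per-patient updates are conditionally
independent given the hyperparameters, so they are vectorised across
patients; population means are conjugate Gaussian updates; scale parameters
use a log-scale random-walk step. Proposal scales adapt during warm-up only,
so post-warm-up draws form a valid Markov chain.

Linear model (fully conjugate patient block):
    d_ij = alpha_i + beta_i * t_ij + eps,   eps ~ N(0, sigma)
    alpha_i ~ N(mu_alpha, tau_alpha),  beta_i ~ N(mu_beta, tau_beta)

Offset-exponential model (patient block via joint random walk on
(log a_i, b_i)):
    d_ij = exp(a_i (t_ij + b_i)) + 2 + eps,  eps ~ N(0, sigma)
    log a_i ~ N(mu_la, tau_la)   (a_i > 0 structurally)
    b_i ~ N(mu_b, tau_b)
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["sample_linear_hierarchy", "sample_exponential_hierarchy"]

# hyperprior scales
_MU_PRIOR_SD = 10.0          # population means of intercept/slope/b (cm, cm/yr, yr)
_MU_LA_PRIOR_MEAN = -2.0     # population mean of log a; a ~ 0.02-0.5 /yr plausible
_MU_LA_PRIOR_SD = 1.5
_TAU_PRIOR_SD = 1.0          # half-normal scale for tau_alpha/beta/la and sigma
_TAU_B_PRIOR_SD = 10.0       # b spreads over many years across detection sizes

_ADAPT_WINDOW = 25
_EXP_CLIP = 60.0             # clamp on the exponent to avoid overflow in proposals


def _halfnormal_logpdf(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


def _update_log_scale(value, step, rng, loglike, prior_sd):
    """One log-scale random-walk Metropolis step for a positive scalar.

    ``loglike(v)`` is the log-likelihood as a function of the scale; the
    half-normal prior and the log-transform Jacobian are added here.
    Returns (new_value, accepted).
    """
    prop = value * math.exp(step * rng.standard_normal())
    cur_lp = loglike(value) + _halfnormal_logpdf(value, prior_sd) + math.log(value)
    prop_lp = loglike(prop) + _halfnormal_logpdf(prop, prior_sd) + math.log(prop)
    if math.log(rng.random()) < prop_lp - cur_lp:
        return prop, True
    return value, False


def _gauss_mean_update(values, tau, rng, prior_mean=0.0, prior_sd=_MU_PRIOR_SD):
    """Conjugate draw of a population mean given iid N(mu, tau) values."""
    n = values.size
    prec = n / tau**2 + 1.0 / prior_sd**2
    mean = (values.sum() / tau**2 + prior_mean / prior_sd**2) / prec
    return rng.normal(mean, math.sqrt(1.0 / prec))


def _normal_ss_loglike(values, mu):
    ss = float(np.sum((values - mu) ** 2))
    n = values.size

    def ll(tau):
        return -n * math.log(tau) - ss / (2.0 * tau**2)

    return ll


class _ScalarAdapter:
    """Robbins-Monro-style step adaptation for a scalar Metropolis move."""

    def __init__(self, step=0.5, target=0.44):
        self.step = step
        self.target = target
        self.accepted = 0
        self.tried = 0

    def record(self, accepted: bool, adapting: bool):
        self.tried += 1
        self.accepted += accepted
        if adapting and self.tried >= _ADAPT_WINDOW:
            rate = self.accepted / self.tried
            self.step = float(np.clip(self.step * math.exp(rate - self.target), 1e-3, 5.0))
            self.accepted = 0
            self.tried = 0


def sample_linear_hierarchy(
    t: np.ndarray,
    d: np.ndarray,
    idx: np.ndarray,
    n_patients: int,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Sample the hierarchical linear model; returns (chain, draw, ...) arrays."""
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    idx = np.asarray(idx, np.intp)
    N = n_patients
    n_i = np.bincount(idx, minlength=N).astype(float)
    St = np.bincount(idx, weights=t, minlength=N)
    Stt = np.bincount(idx, weights=t * t, minlength=N)
    Sd = np.bincount(idx, weights=d, minlength=N)
    Std = np.bincount(idx, weights=t * d, minlength=N)

    # per-patient OLS for initialisation (slope 0 where degenerate)
    det0 = n_i * Stt - St**2
    ok = det0 > 1e-12
    beta0 = np.where(ok, (n_i * Std - St * Sd) / np.where(ok, det0, 1.0), 0.0)
    alpha0 = (Sd - beta0 * St) / n_i

    out = {
        k: np.empty((chains, draws, N))
        for k in ("alpha", "beta")
    }
    hyper = {k: np.empty((chains, draws)) for k in
             ("mu_alpha", "mu_beta", "tau_alpha", "tau_beta", "sigma")}

    ss = np.random.SeedSequence(seed)
    for c, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        alpha = alpha0 + 0.05 * rng.standard_normal(N)
        beta = beta0 + 0.02 * rng.standard_normal(N)
        mu_a, mu_b = float(alpha.mean()), float(beta.mean())
        tau_a = max(float(alpha.std()), 0.05)
        tau_b = max(float(beta.std()), 0.02)
        sigma = 0.15
        adapters = {k: _ScalarAdapter() for k in ("tau_alpha", "tau_beta", "sigma")}

        for it in range(warmup + draws):
            adapting = it < warmup
            # patient block: exact bivariate-normal conditional
            s2 = sigma**2
            A11 = n_i / s2 + 1.0 / tau_a**2
            A12 = St / s2
            A22 = Stt / s2 + 1.0 / tau_b**2
            r1 = Sd / s2 + mu_a / tau_a**2
            r2 = Std / s2 + mu_b / tau_b**2
            det = A11 * A22 - A12**2
            C11, C12, C22 = A22 / det, -A12 / det, A11 / det
            m1 = C11 * r1 + C12 * r2
            m2 = C12 * r1 + C22 * r2
            L11 = np.sqrt(C11)
            L21 = C12 / L11
            L22 = np.sqrt(np.maximum(C22 - L21**2, 1e-300))
            z1 = rng.standard_normal(N)
            z2 = rng.standard_normal(N)
            alpha = m1 + L11 * z1
            beta = m2 + L21 * z1 + L22 * z2

            mu_a = _gauss_mean_update(alpha, tau_a, rng)
            mu_b = _gauss_mean_update(beta, tau_b, rng)

            tau_a, acc = _update_log_scale(
                tau_a, adapters["tau_alpha"].step, rng,
                _normal_ss_loglike(alpha, mu_a), _TAU_PRIOR_SD)
            adapters["tau_alpha"].record(acc, adapting)
            tau_b, acc = _update_log_scale(
                tau_b, adapters["tau_beta"].step, rng,
                _normal_ss_loglike(beta, mu_b), _TAU_PRIOR_SD)
            adapters["tau_beta"].record(acc, adapting)

            resid = d - alpha[idx] - beta[idx] * t
            ssr = float(resid @ resid)
            M = d.size
            tau_s = adapters["sigma"].step
            sigma, acc = _update_log_scale(
                sigma, tau_s, rng,
                lambda s: -M * math.log(s) - ssr / (2.0 * s**2), _TAU_PRIOR_SD)
            adapters["sigma"].record(acc, adapting)

            if it >= warmup:
                j = it - warmup
                out["alpha"][c, j] = alpha
                out["beta"][c, j] = beta
                for key, val in (("mu_alpha", mu_a), ("mu_beta", mu_b),
                                 ("tau_alpha", tau_a), ("tau_beta", tau_b),
                                 ("sigma", sigma)):
                    hyper[key][c, j] = val

    out.update(hyper)
    return out


def sample_exponential_hierarchy(
    t: np.ndarray,
    d: np.ndarray,
    idx: np.ndarray,
    n_patients: int,
    init_la: np.ndarray,
    init_b: np.ndarray,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Sample the hierarchical offset-exponential model.

    ``init_la`` / ``init_b`` are per-patient starting values (typically from
    the log-linear initialiser, falling back to population-scale guesses for
    patients where that fails); each chain jitters them independently.

    Internally the patient block is sampled in (la, v) coordinates with
    v = a * b, i.e. d_ij = exp(a_i t_ij + v_i) + 2. In the natural (la, b)
    coordinates the posterior concentrates on a narrow ridge a*b ~ const
    (both parameters trade off to match the diameter at entry), which cripples
    a random-walk sampler; v is the log-scale intercept and is nearly
    orthogonal to la. The population prior stays on b itself, so the target
    includes the Jacobian of b = v e^{-la} (a -la term in the log-density).
    """
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    idx = np.asarray(idx, np.intp)
    N = n_patients
    M = d.size

    def patient_sse(la, v):
        arg = np.minimum(np.exp(la)[idx] * t + v[idx], _EXP_CLIP)
        resid = d - (np.exp(arg) + 2.0)
        return np.bincount(idx, weights=resid * resid, minlength=N)

    out = {k: np.empty((chains, draws, N)) for k in ("la", "b")}
    hyper = {k: np.empty((chains, draws)) for k in
             ("mu_la", "mu_b", "tau_la", "tau_b", "sigma")}

    ss = np.random.SeedSequence(seed)
    for c, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        la = np.asarray(init_la, float) + 0.05 * rng.standard_normal(N)
        b0 = np.asarray(init_b, float) + 0.05 * rng.standard_normal(N)
        v = np.exp(la) * b0
        b = v * np.exp(-la)
        mu_la = float(la.mean())
        mu_b = float(b.mean())
        tau_la = max(float(la.std()), 0.1)
        tau_b = max(float(b.std()), 0.5)
        sigma = 0.15
        sse = patient_sse(la, v)

        step_la = np.full(N, 0.3)
        step_v = np.full(N, 0.15)
        acc_n = np.zeros(N)
        tried = 0
        adapters = {k: _ScalarAdapter() for k in ("tau_la", "tau_b", "sigma")}

        def patient_logprior(la_, v_, b_):
            lp = -((la_ - mu_la) ** 2) / (2.0 * tau_la**2)
            lp -= ((b_ - mu_b) ** 2) / (2.0 * tau_b**2)
            return lp - la_  # Jacobian of b = v e^{-la}

        for it in range(warmup + draws):
            adapting = it < warmup
            # joint random-walk update of (log a_i, v_i), vectorised over patients
            la_p = la + step_la * rng.standard_normal(N)
            v_p = v + step_v * rng.standard_normal(N)
            b_p = v_p * np.exp(-la_p)
            sse_p = patient_sse(la_p, v_p)
            dll = (sse - sse_p) / (2.0 * sigma**2)
            dlp = patient_logprior(la_p, v_p, b_p) - patient_logprior(la, v, b)
            accept = np.log(rng.random(N)) < dll + dlp
            la = np.where(accept, la_p, la)
            v = np.where(accept, v_p, v)
            b = np.where(accept, b_p, b)
            sse = np.where(accept, sse_p, sse)
            acc_n += accept
            tried += 1
            if adapting and tried >= _ADAPT_WINDOW:
                rate = acc_n / tried
                factor = np.exp(rate - 0.27)  # joint 2-d proposal target
                step_la = np.clip(step_la * factor, 1e-3, 3.0)
                step_v = np.clip(step_v * factor, 1e-3, 3.0)
                acc_n[:] = 0.0
                tried = 0

            mu_la = _gauss_mean_update(la, tau_la, rng,
                                       _MU_LA_PRIOR_MEAN, _MU_LA_PRIOR_SD)
            mu_b = _gauss_mean_update(b, tau_b, rng)

            tau_la, acc = _update_log_scale(
                tau_la, adapters["tau_la"].step, rng,
                _normal_ss_loglike(la, mu_la), _TAU_PRIOR_SD)
            adapters["tau_la"].record(acc, adapting)
            tau_b, acc = _update_log_scale(
                tau_b, adapters["tau_b"].step, rng,
                _normal_ss_loglike(b, mu_b), _TAU_B_PRIOR_SD)
            adapters["tau_b"].record(acc, adapting)

            total_sse = float(sse.sum())
            sigma, acc = _update_log_scale(
                sigma, adapters["sigma"].step, rng,
                lambda s: -M * math.log(s) - total_sse / (2.0 * s**2), _TAU_PRIOR_SD)
            adapters["sigma"].record(acc, adapting)

            if it >= warmup:
                j = it - warmup
                out["la"][c, j] = la
                out["b"][c, j] = b
                for key, val in (("mu_la", mu_la), ("mu_b", mu_b),
                                 ("tau_la", tau_la), ("tau_b", tau_b),
                                 ("sigma", sigma)):
                    hyper[key][c, j] = val

    out.update(hyper)
    return out
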