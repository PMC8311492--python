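"""Hierarchical Bayesian estimation of prospect-theory choice parameters.

Per-subject parameters (lam, rho, tau) are modeled hierarchically: an
unconstrained subject effect eta ~ Normal(mu, sigma) per parameter is
squashed onto its bounded support via the normal CDF,
theta = upper * Phi(eta).  Priors are mu ~ Normal(0, 1) and
sigma ~ HalfNormal(1) on the unconstrained scale.

Posterior inference uses an adaptive gradient-based Gibbs scheme.  Subjects
are conditionally independent given the hyperparameters, so all subject
blocks move in parallel: Hamiltonian sweeps in per-subject whitened
coordinates (the analytic likelihood gradient follows the curved
lam/rho/tau ridge), plus an independence proposal from the approximate full
conditional built from each subject's Laplace approximation.  Collective
translation and scale moves target the slow modes that couple the
hyperparameters to the subject effects, including a correlated 3-d
translation whose covariance comes from the summed per-subject marginal
information about mu.  mu itself has an exact conjugate Gibbs draw and the
log-scale a likelihood-free Metropolis update (with this centering the
hyperparameters do not enter the choice likelihood).  A per-subject
maximum-likelihood fit is provided as an independent oracle and
initializer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr

from .choice_model import ProspectParams, SubjectChoices
from .cleaning import collapse_responses

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "MCMCConfig",
    "MLEResult",
    "HierarchicalPosterior",
    "PPCSummary",
    "log_likelihood",
    "fit_mle",
    "fit_hierarchical",
    "posterior_predictive_check",
]

PARAM_NAMES = ("lam", "rho", "tau")

# Upper bounds of the (0, upper) supports; the printed ranges of published
# estimates fall well inside.  Lower bound is the open 0.
DEFAULT_BOUNDS: dict[str, float] = {"lam": 5.0, "rho": 2.0, "tau": 30.0}

RHAT_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# likelihood


def _flatten_cohort(
    cohort: list[SubjectChoices],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack cleaned binary trials into flat arrays with a subject index."""
    gains, losses, accepts, subj_idx, ids = [], [], [], [], []
    for s, sc in enumerate(cohort):
        acc = collapse_responses(sc.trials["response"])
        ok = acc.notna().to_numpy()
        if ok.sum() == 0:
            raise ValueError(f"subject {sc.subject_id} has no analyzable trials")
        gains.append(sc.trials.loc[ok, "gain"].to_numpy(dtype=float))
        losses.append(sc.trials.loc[ok, "loss"].to_numpy(dtype=float))
        accepts.append(acc[ok].to_numpy(dtype=float))
        subj_idx.append(np.full(int(ok.sum()), s, dtype=np.intp))
        ids.append(sc.subject_id)
    return (
        np.concatenate(gains),
        np.concatenate(losses),
        np.concatenate(accepts),
        np.concatenate(subj_idx),
        ids,
    )


def _loglik_per_subject(
    gains: np.ndarray,
    losses: np.ndarray,
    accepts: np.ndarray,
    subj_idx: np.ndarray,
    n_subj: int,
    lam: np.ndarray,
    rho: np.ndarray,
    tau: np.ndarray,
) -> np.ndarray:
    """Vectorized Bernoulli log likelihood summed within subjects."""
    r = rho[subj_idx]
    sv = 0.5 * gains**r - 0.5 * lam[subj_idx] * losses**r
    logit = tau[subj_idx] * sv
    ll = np.where(
        accepts == 1.0,
        -np.logaddexp(0.0, -logit),
        -np.logaddexp(0.0, logit),
    )
    return np.bincount(subj_idx, weights=ll, minlength=n_subj)


def _loglik_and_grad_theta(
    gains, losses, log_gains, log_losses, accepts, subj_idx, n_subj, theta
):
    """Likelihood and its gradient w.r.t. (lam, rho, tau), per subject."""
    lam, rho, tau = theta[:, 0], theta[:, 1], theta[:, 2]
    r = rho[subj_idx]
    gp = gains**r
    lp = losses**r
    sv = 0.5 * gp - 0.5 * lam[subj_idx] * lp
    logit = tau[subj_idx] * sv
    ll = np.where(
        accepts == 1.0, -np.logaddexp(0.0, -logit), -np.logaddexp(0.0, logit)
    )
    resid = accepts - expit(logit)
    t = tau[subj_idx]
    d_lam = resid * (-0.5 * t * lp)
    d_rho = resid * (0.5 * t * (gp * log_gains - lam[subj_idx] * lp * log_losses))
    d_tau = resid * sv
    grad = np.stack(
        [
            np.bincount(subj_idx, weights=d, minlength=n_subj)
            for d in (d_lam, d_rho, d_tau)
        ],
        axis=1,
    )
    return np.bincount(subj_idx, weights=ll, minlength=n_subj), grad


def log_likelihood(trials: SubjectChoices, params: ProspectParams) -> float:
    """Bernoulli log likelihood of a subject's cleaned binary choices.

    Missing responses (timeouts) are excluded, never imputed.

    Raises
    ------
    ValueError
        If no analyzable trials remain.
    """
    gains, losses, accepts, subj_idx, _ = _flatten_cohort([trials])
    ll = _loglik_per_subject(
        gains,
        losses,
        accepts,
        subj_idx,
        1,
        np.array([params.lam]),
        np.array([params.rho]),
        np.array([params.tau]),
    )
    return float(ll[0])


# ---------------------------------------------------------------------------
# per-subject maximum likelihood (oracle / initializer)


@dataclass
class MLEResult:
    subject_id: str
    params: ProspectParams
    loglik: float
    flagged: bool
    message: str = ""


def fit_mle(
    trials: SubjectChoices,
    bounds: dict[str, float] | None = None,
    n_starts: int = 5,
    seed: int | None = None,
) -> MLEResult:
    """Box-constrained multi-start ML estimate of (lam, rho, tau).

    The result is flagged when no start converges or the optimum sits on the
    parameter box boundary (e.g., a degenerate all-accept subject pushes lam
    to 0 and tau to its cap).
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    gains, losses, accepts, subj_idx, _ = _flatten_cohort([trials])
    rng = np.random.default_rng(seed)

    def neg_ll(x: np.ndarray) -> float:
        ll = _loglik_per_subject(
            gains, losses, accepts, subj_idx, 1, x[:1], x[1:2], x[2:3]
        )
        return -float(ll[0])

    lo = np.full(3, 1e-3)
    hi = np.array([bounds[k] for k in PARAM_NAMES])
    box = list(zip(lo, hi))
    starts = [np.array([1.5, 0.7, 2.0])]
    starts += [lo + rng.uniform(0.05, 0.95, size=3) * (hi - lo) for _ in range(n_starts - 1)]

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B", bounds=box)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x = np.clip(best.x, lo, hi)
    at_edge = bool(np.any(np.isclose(x, lo, atol=2e-3)) or np.any(np.isclose(x, hi, rtol=1e-3)))
    flagged = (not any_success) or at_edge
    return MLEResult(
        subject_id=trials.subject_id,
        params=ProspectParams(lam=float(x[0]), rho=float(x[1]), tau=float(x[2])),
        loglik=-float(best.fun),
        flagged=flagged,
        message="" if not flagged else "non-convergence or boundary solution",
    )


# ---------------------------------------------------------------------------
# hierarchical sampler


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int | None = None
    bounds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    target_accept_subject: float = 0.80  # HMC block acceptance target
    target_accept_group: float = 0.40
    n_eta_sweeps: int = 2
    hmc_steps: int = 10


@dataclass
class HierarchicalPosterior:
    """Posterior draws and diagnostics from :func:`fit_hierarchical`.

    Arrays in ``draws`` are shaped (chain, draw, ...):

    - ``mu``, ``sigma``: (C, D, 3) hyperparameters on the unconstrained scale
    - ``theta``: (C, D, S, 3) per-subject draws on the constrained scale
    - ``group_mean``: (C, D, 3) model-implied population mean of each
      constrained parameter, upper * Phi(mu / sqrt(1 + sigma^2))
    """

    subject_ids: list[str]
    bounds: dict[str, float]
    draws: dict[str, np.ndarray]
    diagnostics: dict
    mean_rt: pd.Series
    flagged: bool = False

    def _flat(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def subject_draws(self, param: str) -> np.ndarray:
        """(total draws, n_subjects) constrained draws of one parameter."""
        return self._flat("theta")[:, :, PARAM_NAMES.index(param)]

    def group_mean(self, param: str) -> tuple[float, float]:
        """Posterior mean and SD of the population mean of ``param``."""
        g = self._flat("group_mean")[:, PARAM_NAMES.index(param)]
        return float(g.mean()), float(g.std(ddof=1))

    def summary(self) -> pd.DataFrame:
        """Per-subject posterior means/SDs plus mean reaction time."""
        theta = self._flat("theta")
        rows = {"subject_id": self.subject_ids}
        for k, name in enumerate(PARAM_NAMES):
            label = "lambda" if name == "lam" else name
            rows[f"{label}_mean"] = theta[:, :, k].mean(axis=0)
            rows[f"{label}_sd"] = theta[:, :, k].std(axis=0, ddof=1)
        df = pd.DataFrame(rows)
        df["mean_rt"] = df["subject_id"].map(self.mean_rt)
        return df


def _laplace_approximations(
    gains, losses, accepts, subj_idx, n_subj, upper
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject likelihood mode and Hessian (precision) in eta space.

    Combined with the current prior precision these form approximate
    full-conditional independence proposals for the subject blocks.
    """
    modes = np.empty((n_subj, 3))
    hessians = np.empty((n_subj, 3, 3))
    box = [(-3.5, 3.5)] * 3

    for s in range(n_subj):
        m = subj_idx == s
        g, l, a = gains[m], losses[m], accepts[m]
        one = np.zeros(int(m.sum()), dtype=np.intp)

        def neg_ll(eta):
            th = upper * ndtr(eta)
            return -float(
                _loglik_per_subject(g, l, a, one, 1, th[:1], th[1:2], th[2:3])[0]
            )

        res = optimize.minimize(
            neg_ll, np.array([-0.5, -0.5, -1.3]), method="L-BFGS-B", bounds=box
        )
        mode = np.clip(res.x, -3.4, 3.4)
        # central finite-difference Hessian
        h = 1e-3
        H = np.empty((3, 3))
        for i in range(3):
            for j in range(i, 3):
                ei, ej = np.eye(3)[i] * h, np.eye(3)[j] * h
                H[i, j] = H[j, i] = (
                    neg_ll(mode + ei + ej)
                    - neg_ll(mode + ei - ej)
                    - neg_ll(mode - ei + ej)
                    + neg_ll(mode - ei - ej)
                ) / (4 * h * h)
        w, V = np.linalg.eigh(0.5 * (H + H.T))
        w = np.clip(w, 1e-3, 1e5)  # PSD likelihood information
        modes[s] = mode
        hessians[s] = (V * w) @ V.T
    return modes, hessians


def _run_chain(
    gains,
    losses,
    accepts,
    subj_idx,
    n_subj,
    upper,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    laplace: tuple[np.ndarray, np.ndarray] | None = None,
):
    n_iter = cfg.n_warmup + cfg.n_draws
    mu = np.array([-0.5, -0.5, -1.3]) + 0.2 * rng.standard_normal(3)
    log_sigma = np.log(0.5) + 0.1 * rng.standard_normal(3)
    eta = mu + np.exp(log_sigma) * rng.standard_normal((n_subj, 3))

    if laplace is not None:
        lap_mode, lap_hess = laplace
        lap_hm = np.einsum("sij,sj->si", lap_hess, lap_mode)  # H_s @ m_s
        lik_info = np.einsum("sii->si", lap_hess).copy()  # per-axis curvature
        eta = lap_mode + 0.1 * rng.standard_normal((n_subj, 3))
    else:
        lik_info = np.zeros((n_subj, 3))

    log_step_eta = np.full(n_subj, np.log(0.2))  # per-subject leapfrog step
    log_step_ls = np.full(3, np.log(0.3))
    log_step_tr = np.full(3, np.log(0.05))  # collective mu/eta translation steps
    log_step_tr3 = np.log(1.0)  # correlated 3-d collective translation scale
    log_step_sc = np.full(3, np.log(0.05))  # collective sigma/eta scale steps

    # Haario-style per-subject proposal preconditioning: running moments of
    # eta feed a covariance estimate whose Cholesky factor shapes proposals
    # (the 3 parameters are strongly correlated in the choice likelihood).
    chol = np.tile(0.3 * np.eye(3), (n_subj, 1, 1))
    run_n = 0
    run_mean = np.zeros((n_subj, 3))
    run_m2 = np.zeros((n_subj, 3, 3))

    log_gains, log_losses = np.log(gains), np.log(losses)

    def loglik(etav):
        th = upper * ndtr(etav)
        return _loglik_per_subject(
            gains, losses, accepts, subj_idx, n_subj, th[:, 0], th[:, 1], th[:, 2]
        )

    def loglik_grad(etav):
        """Likelihood and full-conditional gradient in eta space."""
        th = upper * ndtr(etav)
        ll_s, g_theta = _loglik_and_grad_theta(
            gains, losses, log_gains, log_losses, accepts, subj_idx, n_subj, th
        )
        d_theta = upper * np.exp(-0.5 * etav**2) / np.sqrt(2.0 * np.pi)
        g_eta = g_theta * d_theta - (etav - mu) / sigma**2
        return ll_s, g_eta

    sigma = np.exp(log_sigma)
    ll = loglik(eta)

    keep_theta = np.empty((cfg.n_draws, n_subj, 3))
    keep_mu = np.empty((cfg.n_draws, 3))
    keep_sigma = np.empty((cfg.n_draws, 3))
    acc_stats = {
        "indep": 0.0,
        "mala": 0.0,
        "translate": np.zeros(3),
        "translate3": 0.0,
        "scale": np.zeros(3),
    }

    for t in range(n_iter):
        adapt = t < cfg.n_warmup
        gamma = 1.0 / (t + 10) ** 0.6  # Robbins-Monro decay

        if adapt:
            run_n += 1
            delta = eta - run_mean
            run_mean += delta / run_n
            run_m2 += np.einsum("si,sj->sij", delta, eta - run_mean)
            if run_n >= 50 and t % 25 == 0:
                cov = run_m2 / (run_n - 1) + 1e-6 * np.eye(3)
                chol = np.linalg.cholesky(cov)

        # --- per-subject independence proposals from the approximate full
        # conditional N(P^-1 b, P^-1), P = H_s + diag(1/sigma^2),
        # b = H_s m_s + mu / sigma^2.  Near-iid moves when the Laplace
        # approximation is accurate; the log-determinant cancels in the
        # acceptance ratio because forward and reverse share P.
        if laplace is not None:
            P = lap_hess + np.diag(1.0 / sigma**2)  # broadcast over subjects
            b = lap_hm + mu / sigma**2
            mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
            Lp = np.linalg.cholesky(P)
            # sample x = mean + L^-T eps
            eps = rng.standard_normal((n_subj, 3))
            perturb = np.linalg.solve(
                np.swapaxes(Lp, 1, 2), eps[:, :, None]
            )[:, :, 0]
            eta_prop = mean + perturb

            def cond_logq(etav):
                d = etav - mean
                return -0.5 * np.einsum("si,sij,sj->s", d, P, d)

            ll_prop = loglik(eta_prop)
            dprior = -0.5 * np.sum(
                ((eta_prop - mu) ** 2 - (eta - mu) ** 2) / sigma**2, axis=1
            )
            log_alpha = ll_prop - ll + dprior + cond_logq(eta) - cond_logq(eta_prop)
            accept_mask = np.log(rng.uniform(size=n_subj)) < log_alpha
            eta[accept_mask] = eta_prop[accept_mask]
            ll[accept_mask] = ll_prop[accept_mask]
            if not adapt:
                acc_stats["indep"] += accept_mask.mean() / cfg.n_draws

        # --- Hamiltonian sweeps over the per-subject eta blocks, vectorized
        # across subjects in whitened coordinates y = L^-1 eta (L from each
        # subject's adapted posterior covariance).  The three parameters ride
        # a curved likelihood ridge that defeats single-step proposals;
        # leapfrog trajectories follow it.
        for _ in range(cfg.n_eta_sweeps):
            ll_cur, grad_cur = loglik_grad(eta)
            lp_cur = ll_cur - 0.5 * np.sum((eta - mu) ** 2 / sigma**2, axis=1)
            n_leap = int(rng.integers(cfg.hmc_steps // 2, cfg.hmc_steps + 1))
            eps_s = np.exp(log_step_eta)[:, None]
            p = rng.standard_normal((n_subj, 3))
            h0 = -lp_cur + 0.5 * np.sum(p**2, axis=1)

            q = eta.copy()
            # grad in whitened coords: g_y = L^T grad_eta
            g_y = np.einsum("sji,sj->si", chol, grad_cur)
            p_run = p + 0.5 * eps_s * g_y
            for step in range(n_leap):
                q = q + eps_s * np.einsum("sij,sj->si", chol, p_run)
                ll_new, grad_new = loglik_grad(q)
                g_y = np.einsum("sji,sj->si", chol, grad_new)
                p_run = p_run + (eps_s if step < n_leap - 1 else 0.5 * eps_s) * g_y
            lp_new = ll_new - 0.5 * np.sum((q - mu) ** 2 / sigma**2, axis=1)
            h1 = -lp_new + 0.5 * np.sum(p_run**2, axis=1)

            log_alpha = np.where(np.isfinite(h1), h0 - h1, -np.inf)
            accept_mask = np.log(rng.uniform(size=n_subj)) < log_alpha
            eta[accept_mask] = q[accept_mask]
            ll[accept_mask] = ll_new[accept_mask]
            if adapt:
                log_step_eta += gamma * (
                    np.exp(np.minimum(log_alpha, 0.0)) - cfg.target_accept_subject
                )
            else:
                acc_stats["mala"] += accept_mask.mean() / (cfg.n_draws * cfg.n_eta_sweeps)

        # --- collective translation moves: shift mu_k together with every
        # eta_k, each subject weighted by its prior dominance
        # kappa_s = prior precision / (prior + likelihood precision), so the
        # proposal follows the posterior's soft collective mode: weakly
        # identified subjects ride along with mu while well-pinned subjects
        # stay near their likelihood modes.  The shift is linear and
        # volume-preserving, so no Jacobian term appears.
        prior_prec = 1.0 / sigma**2
        kappa = prior_prec / (prior_prec + lik_info)  # (S, 3)

        # correlated 3-d variant: the group-level posterior has a ridge
        # (e.g. lower curvature trading off against higher sensitivity for
        # the whole cohort) that axis-aligned shifts cannot follow.  The
        # collective-mode covariance is available analytically: subject s
        # contributes marginal information M_s = (H_s^-1 + P^-1)^-1 about mu
        # (H_s the Laplace Hessian, P the prior precision), and each
        # subject's posterior mean responds to a prior-mean shift delta by
        # K_s delta with K_s = (H_s + P)^-1 P.
        if laplace is not None:
            Pm = np.diag(prior_prec)
            Ainv = np.linalg.inv(lap_hess + Pm)  # (S, 3, 3)
            K = Ainv @ Pm
            M = Pm - Pm @ Ainv @ Pm
            chol_col = np.linalg.cholesky(
                np.linalg.inv(M.sum(axis=0) + np.eye(3))
            )
            delta3 = np.exp(log_step_tr3) * (chol_col @ rng.standard_normal(3))
            eta_prop = eta + np.einsum("sij,j->si", K, delta3)
            mu_prop3 = mu + delta3
            ll_prop = loglik(eta_prop)
            dev_new = eta_prop - mu_prop3
            dev_old = eta - mu
            log_alpha3 = (
                ll_prop.sum()
                - ll.sum()
                - 0.5 * np.sum(prior_prec * (dev_new**2 - dev_old**2))
                - 0.5 * np.sum(mu_prop3**2 - mu**2)
            )
            tr3_ok = float(np.log(rng.uniform()) < log_alpha3)
            if tr3_ok:
                eta, mu, ll = eta_prop, mu_prop3, ll_prop
            if adapt:
                log_step_tr3 += gamma * (tr3_ok - 0.30)
            else:
                acc_stats["translate3"] += tr3_ok / cfg.n_draws

        for k in range(3):
            delta = np.exp(log_step_tr[k]) * rng.standard_normal()
            eta_prop = eta.copy()
            eta_prop[:, k] += delta * kappa[:, k]
            ll_prop = loglik(eta_prop)
            dev_new = eta_prop[:, k] - (mu[k] + delta)
            dev_old = eta[:, k] - mu[k]
            log_alpha_tr = (
                ll_prop.sum()
                - ll.sum()
                - 0.5 * prior_prec[k] * np.sum(dev_new**2 - dev_old**2)
                - 0.5 * ((mu[k] + delta) ** 2 - mu[k] ** 2)
            )
            tr_ok = float(np.log(rng.uniform()) < log_alpha_tr)
            if tr_ok:
                eta, ll = eta_prop, ll_prop
                mu = mu.copy()
                mu[k] += delta
            if adapt:
                log_step_tr[k] += gamma * (tr_ok - 0.44)
            elif tr_ok:
                acc_stats["translate"][k] += 1.0 / cfg.n_draws

        # --- collective scale moves: rescale the eta_k spread together with
        # sigma_k (the complementary collective mode; the eta prior term is
        # invariant, leaving the likelihood, sigma prior and Jacobian).
        for k in range(3):
            c = np.exp(np.exp(log_step_sc[k]) * rng.standard_normal())
            eta_prop = eta.copy()
            eta_prop[:, k] = mu[k] + c * (eta[:, k] - mu[k])
            ll_prop = loglik(eta_prop)
            log_alpha_sc = (
                ll_prop.sum()
                - ll.sum()
                - 0.5 * (c**2 - 1.0) * sigma[k] ** 2
                + np.log(c)
            )
            sc_ok = float(np.log(rng.uniform()) < log_alpha_sc)
            if sc_ok:
                eta, ll = eta_prop, ll_prop
                log_sigma = log_sigma.copy()
                log_sigma[k] += np.log(c)
                sigma = np.exp(log_sigma)
            if adapt:
                log_step_sc[k] += gamma * (sc_ok - 0.44)
            elif sc_ok:
                acc_stats["scale"][k] += 1.0 / cfg.n_draws

        # --- mu: exact conjugate Gibbs draw (prior N(0,1), eta ~ N(mu, sigma))
        prec = 1.0 + n_subj / sigma**2
        mean = (eta.sum(axis=0) / sigma**2) / prec
        mu = mean + rng.standard_normal(3) / np.sqrt(prec)

        # --- log sigma: likelihood-free Metropolis (HalfNormal(1) prior on
        # sigma; +log_sigma is the Jacobian of sampling on the log scale)
        dev2 = ((eta - mu) ** 2).sum(axis=0)

        def scale_logpost(ls):
            s2 = np.exp(2 * ls)
            return -0.5 * dev2 / s2 - n_subj * ls - 0.5 * s2 + ls

        for _ in range(2):
            ls_prop = log_sigma + np.exp(log_step_ls) * rng.standard_normal(3)
            log_alpha3 = scale_logpost(ls_prop) - scale_logpost(log_sigma)
            ok = np.log(rng.uniform(size=3)) < log_alpha3
            log_sigma = np.where(ok, ls_prop, log_sigma)
            if adapt:
                log_step_ls += gamma * (ok.astype(float) - cfg.target_accept_group)
        sigma = np.exp(log_sigma)

        if not adapt:
            d = t - cfg.n_warmup
            keep_theta[d] = upper * ndtr(eta)
            keep_mu[d] = mu
            keep_sigma[d] = sigma

    acc_stats["step_translate"] = np.exp(log_step_tr)
    acc_stats["step_scale"] = np.exp(log_step_sc)
    acc_stats["step_eta"] = float(np.exp(log_step_eta).mean())
    return keep_mu, keep_sigma, keep_theta, acc_stats


def fit_hierarchical(
    cohort: list[SubjectChoices], config: MCMCConfig | None = None
) -> HierarchicalPosterior:
    """Fit the hierarchical prospect-theory model to a cleaned cohort.

    Runs ``config.n_chains`` independent adaptive Metropolis-within-Gibbs
    chains and populates split-chain convergence diagnostics (rank-normalized
    R-hat and bulk effective sample size via arviz).  The result is flagged
    with a warning when any hyperparameter R-hat exceeds 1.1.

    Raises
    ------
    ValueError
        If the cohort has fewer than 2 subjects.
    """
    cfg = config or MCMCConfig()
    if len(cohort) < 2:
        raise ValueError("hierarchical fit requires >= 2 subjects")
    gains, losses, accepts, subj_idx, ids = _flatten_cohort(cohort)
    n_subj = len(ids)
    upper = np.array([cfg.bounds[k] for k in PARAM_NAMES])

    laplace = _laplace_approximations(gains, losses, accepts, subj_idx, n_subj, upper)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    mus, sigmas, thetas, accs = [], [], [], []
    for ss in seeds:
        m, s, th, acc = _run_chain(
            gains, losses, accepts, subj_idx, n_subj, upper, cfg,
            np.random.default_rng(ss), laplace=laplace,
        )
        mus.append(m)
        sigmas.append(s)
        thetas.append(th)
        accs.append(acc)
    mu = np.stack(mus)  # (C, D, 3)
    sigma = np.stack(sigmas)
    theta = np.stack(thetas)  # (C, D, S, 3)
    group_mean = upper * ndtr(mu / np.sqrt(1.0 + sigma**2))

    diagnostics = _diagnostics(mu, sigma, group_mean)
    diagnostics["sampler"] = [
        {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in a.items()}
        for a in accs
    ]
    flagged = any(v > RHAT_THRESHOLD for v in diagnostics["rhat"].values())
    if flagged:
        warnings.warn(
            f"hierarchical fit did not converge (max R-hat "
            f"{max(diagnostics['rhat'].values()):.3f} > {RHAT_THRESHOLD})",
            stacklevel=2,
        )

    mean_rt = pd.Series(
        {sc.subject_id: float(sc.trials["rt"].mean()) for sc in cohort}, name="mean_rt"
    )
    return HierarchicalPosterior(
        subject_ids=ids,
        bounds=dict(cfg.bounds),
        draws={"mu": mu, "sigma": sigma, "theta": theta, "group_mean": group_mean},
        diagnostics=diagnostics,
        mean_rt=mean_rt,
        flagged=flagged,
    )


def _diagnostics(mu, sigma, group_mean) -> dict:
    import logging

    import arviz as az

    data = {}
    for k, name in enumerate(PARAM_NAMES):
        data[f"mu_{name}"] = mu[:, :, k]
        data[f"sigma_{name}"] = sigma[:, :, k]
        data[f"group_mean_{name}"] = group_mean[:, :, k]
    az_logger = logging.getLogger("arviz")
    level = az_logger.level
    try:
        az_logger.setLevel(logging.ERROR)  # single-chain shape notices
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(posterior=data)
            rhat = az.rhat(idata)
            ess = az.ess(idata)
    finally:
        az_logger.setLevel(level)
    return {
        "rhat": {k: float(rhat[k].values) for k in data},
        "ess_bulk": {k: float(ess[k].values) for k in data},
    }


# ---------------------------------------------------------------------------
# posterior predictive check


@dataclass
class PPCSummary:
    """Observed vs replicated acceptance rates per gain and loss level."""

    table: pd.DataFrame  # columns: predictor, level, observed, pred_mean, lo, hi, inside
    interval: float

    @property
    def coverage(self) -> float:
        """Fraction of bins whose observed rate falls in the predictive interval."""
        return float(self.table["inside"].mean())


def posterior_predictive_check(
    posterior: HierarchicalPosterior,
    cohort: list[SubjectChoices],
    n_rep: int = 200,
    interval: float = 0.90,
    seed: int | None = None,
) -> PPCSummary:
    """Simulate replicated cohorts from posterior draws and compare
    cohort-level acceptance rates per gain level and per loss level against
    central predictive intervals.

    Raises
    ------
    ValueError
        If ``n_rep`` < 1.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    gains, losses, accepts, subj_idx, ids = _flatten_cohort(cohort)
    if ids != posterior.subject_ids:
        raise ValueError("cohort subjects do not match the fitted posterior")
    theta = posterior._flat("theta")  # (N, S, 3)

    draw_idx = rng.integers(0, theta.shape[0], size=n_rep)
    lam = theta[draw_idx][:, :, 0][:, subj_idx]  # (n_rep, n_trials)
    rho = theta[draw_idx][:, :, 1][:, subj_idx]
    tau = theta[draw_idx][:, :, 2][:, subj_idx]
    sv = 0.5 * gains[None, :] ** rho - 0.5 * lam * losses[None, :] ** rho
    p = 1.0 / (1.0 + np.exp(-tau * sv))
    rep_accept = rng.uniform(size=p.shape) < p

    lo_q, hi_q = 50 * (1 - interval), 50 * (1 + interval)
    rows = []
    for predictor, x in (("gain", gains), ("loss", losses)):
        for level in np.unique(x):
            mask = x == level
            obs = float(accepts[mask].mean())
            rep_rates = rep_accept[:, mask].mean(axis=1)
            lo, hi = np.percentile(rep_rates, [lo_q, hi_q])
            rows.append(
                {
                    "predictor": predictor,
                    "level": float(level),
                    "observed": obs,
                    "pred_mean": float(rep_rates.mean()),
                    "lo": float(lo),
                    "hi": float(hi),
                    "inside": bool(lo <= obs <= hi),
                }
            )
    return PPCSummary(table=pd.DataFrame(rows), interval=interval)
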