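"""Metropolis-within-Gibbs sampler with data augmentation.

The posterior over (θ, n0, s_1..s_n) is explored by interleaving, each
iteration:

1. blockwise Gaussian random-walk Metropolis updates of β, α, ξ and log σ
   (the movement scale is updated on the log scale with the Jacobian
   correction, under a Uniform(0, σ_max) prior);
2. per-individual random-walk updates of the latent activity centers,
   proposals falling outside the habitat being rejected outright;
3. an exact Gibbs draw of the never-detected count n0 ~ Poisson(π0·Λ(B)),
   which is its full conditional under the augmented likelihood.

Proposal scales adapt toward target acceptance rates during burn-in only
and are frozen afterwards, so the post-burn-in chain targets the exact
posterior.  For piecewise-constant temporal covariates the likelihood
depends on the detection times only through per-pair counts and the summed
covariate values at event times; the inner loop exploits this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geometry import Domain, TrapArray, squared_distances
from .model import (
    ConfigurationError,
    LatentState,
    Params,
    SurveyData,
    baseline_rates,
    full_loglik,
    lambda_integral,
    pi0,
    restricted_loglik,
)
from .schedule import Schedule

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorChain",
    "update_n0",
    "update_centers",
    "update_theta",
    "run_chain",
    "summarize_chain",
]


@dataclass
class PriorSpec:
    """Independent weakly-informative priors.

    Each coefficient of β, α and ξ gets a Normal(mean, sd²) prior; the
    movement scale σ gets Uniform(0, σ_max).  ``sigma_max=None`` defaults
    to half the domain diameter at fitting time.
    """

    coef_mean: float = 0.0
    coef_sd: float = 10.0
    sigma_max: float | None = None

    def __post_init__(self) -> None:
        if self.coef_sd <= 0:
            raise ConfigurationError("prior sd must be positive")
        if self.sigma_max is not None and self.sigma_max <= 0:
            raise ConfigurationError("sigma_max must be positive")


@dataclass
class MCMCConfig:
    iterations: int = 1200
    burn_in: int = 200
    proposal_scales: dict | None = None  # per-block overrides
    adapt: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations <= 0 or not (0 <= self.burn_in < self.iterations):
            raise ConfigurationError("need 0 <= burn_in < iterations")


@dataclass
class PosteriorChain:
    """Post-burn-in MCMC draws and bookkeeping."""

    param_names: list[str]
    params: np.ndarray  # (kept, P)
    n0: np.ndarray  # (kept,)
    centers: np.ndarray  # (kept, n, 2)
    acceptance: dict[str, float]
    model: str
    seed: int | None
    n_observed: int

    def __len__(self) -> int:
        return self.params.shape[0]

    def column(self, name: str) -> np.ndarray:
        if name == "n0":
            return self.n0.astype(float)
        return self.params[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (iteration, parameter, value) export."""
        kept = len(self)
        frames = []
        for j, name in enumerate(self.param_names):
            frames.append(
                pd.DataFrame(
                    {"iteration": np.arange(kept), "parameter": name, "value": self.params[:, j]}
                )
            )
        frames.append(
            pd.DataFrame(
                {"iteration": np.arange(kept), "parameter": "n0", "value": self.n0.astype(float)}
            )
        )
        return pd.concat(frames, ignore_index=True)

    def params_at(self, i: int, p_beta: int, p_alpha: int, q: int) -> Params:
        row = self.params[i]
        return Params(
            beta=row[:p_beta],
            alpha=row[p_beta : p_beta + p_alpha],
            xi=row[p_beta + p_alpha : p_beta + p_alpha + q],
            sigma=row[-1],
        )


# ---------------------------------------------------------------------------
# reference single-step operations (simple paths built on model.py)
# ---------------------------------------------------------------------------


def update_n0(
    params: Params,
    domain: Domain,
    traps: TrapArray,
    schedule: Schedule | None,
    rng: np.random.Generator,
) -> int:
    """Exact Gibbs draw of the never-detected count: n0 ~ Poisson(π0 Λ(B))."""
    mean = pi0(params, domain, traps, schedule) * lambda_integral(params, domain)
    return int(rng.poisson(mean))


def _center_conditional(
    params: Params,
    centers: np.ndarray,
    data: SurveyData,
    domain: Domain,
    schedule: Schedule,
) -> np.ndarray:
    """Per-individual log target: log λ(s_i) − Σ_k Φ_ik − Σ_k y_ik d²_ik/(2σ²)."""
    traps = data.traps
    v = domain.covariates_at(centers)
    loglam = v @ params.beta
    d2 = np.sum((centers[:, None, :] - traps.locations[None, :, :]) ** 2, axis=2)
    psi = baseline_rates(params, traps)
    eff = schedule.effective_durations(params.xi)
    G = np.exp(-d2 / (2.0 * params.sigma**2))
    return loglam - G @ (psi * eff) - (data.y * d2).sum(axis=1) / (2.0 * params.sigma**2)


def update_centers(
    state: LatentState,
    params: Params,
    data: SurveyData,
    domain: Domain,
    schedule: Schedule,
    rng: np.random.Generator,
    scale: float = 0.25,
) -> LatentState:
    """One sweep of per-individual Gaussian random-walk Metropolis updates."""
    centers = state.centers.copy()
    if centers.shape[0] == 0:
        return LatentState(centers, state.n0)
    prop = centers + scale * rng.standard_normal(centers.shape)
    ok = domain.is_habitat(prop)
    cur_ll = _center_conditional(params, centers, data, domain, schedule)
    prop_safe = np.where(ok[:, None], prop, centers)
    prop_ll = _center_conditional(params, prop_safe, data, domain, schedule)
    accept = ok & (np.log(rng.uniform(size=centers.shape[0])) < prop_ll - cur_ll)
    centers[accept] = prop[accept]
    return LatentState(centers, state.n0)


def _log_prior_coefs(params: Params, prior: PriorSpec) -> float:
    x = np.concatenate([params.beta, params.alpha, params.xi])
    return float(-0.5 * np.sum(((x - prior.coef_mean) / prior.coef_sd) ** 2))


def update_theta(
    state: LatentState,
    params: Params,
    data: SurveyData,
    domain: Domain,
    schedule: Schedule | None,
    prior: PriorSpec,
    rng: np.random.Generator,
    scales: dict | None = None,
    model: str = "full",
) -> Params:
    """One sweep of blockwise random-walk Metropolis updates of θ.

    Reference implementation evaluating the full log-likelihood per block;
    :func:`run_chain` uses an algebraically identical cached fast path.
    """
    scales = dict(scales or {})
    sig_max = prior.sigma_max or domain.diameter / 2.0

    def loglik(p: Params) -> float:
        if model == "full":
            return full_loglik(p, state, data, domain, schedule)
        return restricted_loglik(p, state, data, domain)

    cur = Params(params.beta, params.alpha, params.xi, params.sigma)
    cur_ll = loglik(cur) + _log_prior_coefs(cur, prior)
    for block in ("beta", "alpha", "xi", "sigma"):
        if block == "xi" and cur.xi.size == 0:
            continue
        s = scales.get(block, 0.05)
        prop = Params(cur.beta.copy(), cur.alpha.copy(), cur.xi.copy(), cur.sigma)
        jac = 0.0
        if block == "sigma":
            new_ls = np.log(cur.sigma) + s * rng.standard_normal()
            prop.sigma = float(np.exp(new_ls))
            if prop.sigma >= sig_max:
                rng.uniform()
                continue
            jac = new_ls - np.log(cur.sigma)  # d sigma / d log sigma
        else:
            vec = getattr(prop, block)
            setattr(prop, block, vec + s * rng.standard_normal(vec.size))
        prop_ll = loglik(prop) + _log_prior_coefs(prop, prior)
        if np.log(rng.uniform()) < prop_ll - cur_ll + jac:
            cur, cur_ll = prop, prop_ll
    return cur


# ---------------------------------------------------------------------------
# fast cached posterior evaluator used by run_chain
# ---------------------------------------------------------------------------


class _FastPosterior:
    """Sufficient-statistic likelihood components with per-block caching.

    For piecewise-constant z(t) the full log-likelihood decomposes into
    terms depending on (β), (α, ξ, σ) via cell and individual kernels, and
    the event-level statistics (per-pair counts y, Σ_events z).
    """

    def __init__(
        self,
        data: SurveyData,
        domain: Domain,
        schedule: Schedule,
        model: str,
    ) -> None:
        self.model = model
        self.domain = domain
        self.traps = data.traps
        self.schedule = schedule
        self.V = domain.active_v
        self.area = domain.cell_area
        self.d2_cells = squared_distances(domain, data.traps)  # (A, K)
        self.W = data.traps.w
        self.T = data.traps.durations
        self.y = data.y.astype(float)
        self.ycol = self.y.sum(axis=0)
        self.y_tot = float(self.y.sum())
        self.ylogfact = float(gammaln(data.y + 1).sum())
        if model == "full":
            self.zsum = data.z_sums(schedule)
            self.time_const = 0.0
        else:
            self.zsum = np.zeros(0)
            # counts-only Poisson(T_k φ) likelihood: Σ_ik y_ik log T_k
            self.time_const = float(self.ycol @ np.log(self.T))

    # component computations -------------------------------------------------

    def lam_parts(self, beta):
        loglam = self.V @ beta
        lam = np.exp(loglam)
        return lam, float(lam.sum() * self.area)

    def cell_kernel(self, sigma):
        return np.exp(-self.d2_cells / (2.0 * sigma**2))

    def psi(self, alpha):
        return np.exp(self.W @ alpha)

    def effdur(self, xi):
        if self.model == "full":
            return self.schedule.effective_durations(xi)
        return self.T

    def log_pi0lam(self, lam, E_cells):
        # log[π0 Λ(B)] = log Σ_m λ_m exp(−Σ_k Φ_mk) Δ
        return float(np.log((lam * np.exp(-E_cells)).sum() * self.area))

    def ind_terms(self, Gc, d2c, psi, eff, alpha, xi, sigma):
        """Σ_ik per-pair observation log-density (excluding log λ(s_i))."""
        phi_sum = float((Gc @ (psi * eff)).sum())
        out = (
            -phi_sum
            + float(self.ycol @ (self.W @ alpha))
            - float((self.y * d2c).sum()) / (2.0 * sigma**2)
            - self.ylogfact
            + self.time_const
        )
        if self.model == "full" and xi.size:
            out += float(self.zsum @ xi)
        return out


def fast_loglik(
    params: Params,
    latent: LatentState,
    data: SurveyData,
    domain: Domain,
    schedule: Schedule | None,
    model: str = "full",
) -> float:
    """Log-likelihood assembled from the cached sufficient-statistic
    components; algebraically identical to :func:`ctscr.model.full_loglik`
    (or ``restricted_loglik``) and used by :func:`run_chain`."""
    if model != "full" or schedule is None:
        schedule = Schedule.constant(data.traps.durations)
    fp = _FastPosterior(data, domain, schedule, model)
    lam, Lam = fp.lam_parts(params.beta)
    psi = fp.psi(params.alpha)
    eff = fp.effdur(params.xi)
    E = fp.cell_kernel(params.sigma) @ (psi * eff)
    lp0l = fp.log_pi0lam(lam, E)
    centers = latent.centers
    d2c = (
        np.sum((centers[:, None, :] - data.traps.locations[None, :, :]) ** 2, axis=2)
        if data.n
        else np.zeros((0, data.traps.n_traps))
    )
    Gc = np.exp(-d2c / (2.0 * params.sigma**2))
    ind = fp.ind_terms(Gc, d2c, psi, eff, params.alpha, params.xi, params.sigma)
    vcb = float((domain.covariates_at(centers) @ params.beta).sum()) if data.n else 0.0
    return float(-Lam + latent.n0 * lp0l - gammaln(latent.n0 + 1) + vcb + ind)


def _initial_state(
    data: SurveyData,
    domain: Domain,
    schedule: Schedule,
    model: str,
    prior: PriorSpec,
) -> tuple[Params, LatentState]:
    """Data-driven starting values (centers at detection centroids, moment
    matching for σ and the encounter-rate intercept)."""
    traps = data.traps
    n = data.n
    q = schedule.q if model == "full" else 0
    if n:
        wts = np.maximum(data.y, 0).astype(float)
        tot = wts.sum(axis=1, keepdims=True)
        centers = (wts @ traps.locations) / np.where(tot > 0, tot, 1.0)
        bad = ~domain.is_habitat(centers)
        if bad.any():
            act = domain.active_centers
            for i in np.where(bad)[0]:
                j = np.argmin(np.sum((act - centers[i]) ** 2, axis=1))
                centers[i] = act[j]
    else:
        centers = np.empty((0, 2))
    d2c = (
        np.sum((centers[:, None, :] - traps.locations[None, :, :]) ** 2, axis=2)
        if n
        else np.zeros((0, traps.n_traps))
    )
    y_tot = data.y.sum()
    if y_tot > 0:
        s2 = float((data.y * d2c).sum()) / y_tot
        sigma0 = max(np.sqrt(max(s2, 0.0)), domain.resolution / 2.0)
    else:
        sigma0 = domain.diameter / 10.0
    sig_max = prior.sigma_max or domain.diameter / 2.0
    sigma0 = min(sigma0, 0.8 * sig_max)
    # match total detections with intercept-only encounter rate
    eff = schedule.effective_durations(np.zeros(q)) if model == "full" else traps.durations
    G0 = np.exp(-d2c / (2.0 * sigma0**2))
    denom = float((G0 * eff[None, :]).sum()) if n else 1.0
    alpha0 = np.log(max(y_tot, 1.0) / max(denom, 1e-12)) if n else 0.0
    alpha = np.zeros(traps.w.shape[1])
    alpha[0] = alpha0
    beta = np.zeros(domain.n_covariates)
    beta[0] = np.log(max(n, 1) / domain.total_area)
    params = Params(beta=beta, alpha=alpha, xi=np.zeros(q), sigma=sigma0)
    return params, LatentState(centers, n0=0)


def run_chain(
    data: SurveyData,
    domain: Domain,
    schedule: Schedule | None,
    prior: PriorSpec,
    config: MCMCConfig,
    model: str = "full",
) -> PosteriorChain:
    """Fit the full or restricted model and return post-burn-in draws.

    Deterministic given ``config.seed``: independent child streams are
    spawned for the θ-blocks, the center updates and the n0 draw, so the
    draws at iteration t do not depend on the total iteration count.
    """
    if model not in ("full", "restricted"):
        raise ConfigurationError("model must be 'full' or 'restricted'")
    if model == "full":
        if schedule is None:
            schedule = Schedule.constant(data.traps.durations)
    else:
        schedule = Schedule.constant(data.traps.durations)
    if schedule.n_traps != data.traps.n_traps:
        raise ConfigurationError("schedule must have one entry per trap")

    ss = np.random.SeedSequence(config.seed)
    rng_theta, rng_centers, rng_n0 = (np.random.default_rng(s) for s in ss.spawn(3))

    fp = _FastPosterior(data, domain, schedule, model)
    params, latent = _initial_state(data, domain, schedule, model, prior)
    n = data.n
    q = params.xi.size
    sig_max = prior.sigma_max or domain.diameter / 2.0

    # current cached components
    beta, alpha, xi, sigma = params.beta, params.alpha, params.xi, params.sigma
    centers = latent.centers
    lam, Lam = fp.lam_parts(beta)
    G_cells = fp.cell_kernel(sigma)
    psi = fp.psi(alpha)
    eff = fp.effdur(xi)
    E_cells = G_cells @ (psi * eff)
    lp0l = fp.log_pi0lam(lam, E_cells)
    d2c = (
        np.sum((centers[:, None, :] - data.traps.locations[None, :, :]) ** 2, axis=2)
        if n
        else np.zeros((0, data.traps.n_traps))
    )
    Gc = np.exp(-d2c / (2.0 * sigma**2))
    ind = fp.ind_terms(Gc, d2c, psi, eff, alpha, xi, sigma)
    vcb = float((domain.covariates_at(centers) @ beta).sum()) if n else 0.0
    n0 = int(rng_n0.poisson(np.exp(lp0l)))

    if not np.isfinite(ind + lp0l + Lam):
        raise RuntimeError("non-finite log-posterior at initialization")

    y_tot = max(fp.y_tot, 1.0)
    default_scales = {
        "beta": 1.0 / np.sqrt(max(n, 4)),
        "alpha": 1.0 / np.sqrt(y_tot),
        "xi": 2.0 / np.sqrt(y_tot),
        "sigma": 1.0 / np.sqrt(2.0 * y_tot),
        "centers": max(sigma / 2.0, domain.resolution),
    }
    if config.proposal_scales:
        default_scales.update(config.proposal_scales)
    log_scales = {k: np.log(v) for k, v in default_scales.items()}
    targets = {"beta": 0.25, "alpha": 0.25, "xi": 0.44, "sigma": 0.44, "centers": 0.35}
    acc_counts = {k: 0.0 for k in log_scales}
    acc_total = {k: 0.0 for k in log_scales}

    kept = config.iterations - config.burn_in
    P = beta.size + alpha.size + q + 1
    names = (
        [f"beta_{j}" for j in range(beta.size)]
        + [f"alpha_{j}" for j in range(alpha.size)]
        + [f"xi_{j}" for j in range(q)]
        + ["sigma"]
    )
    out_params = np.empty((kept, P))
    out_n0 = np.empty(kept, dtype=int)
    out_centers = np.empty((kept, n, 2))
    prior_q = lambda v: float(-0.5 * np.sum(((v - prior.coef_mean) / prior.coef_sd) ** 2))

    for it in range(config.iterations):
        in_burn = it < config.burn_in

        # ---- θ blocks ----------------------------------------------------
        for block in ("beta", "alpha", "xi", "sigma"):
            if block == "xi" and (q == 0):
                continue
            s = np.exp(log_scales[block])
            accepted = False
            if block == "beta":
                prop = beta + s * rng_theta.standard_normal(beta.size)
                lam_p, Lam_p = fp.lam_parts(prop)
                lp0l_p = fp.log_pi0lam(lam_p, E_cells)
                vcb_p = float((domain.covariates_at(centers) @ prop).sum()) if n else 0.0
                delta = (
                    (-Lam_p + n0 * lp0l_p + vcb_p + prior_q(prop))
                    - (-Lam + n0 * lp0l + vcb + prior_q(beta))
                )
                if np.log(rng_theta.uniform()) < delta:
                    beta, lam, Lam, lp0l, vcb = prop, lam_p, Lam_p, lp0l_p, vcb_p
                    accepted = True
            elif block == "alpha":
                prop = alpha + s * rng_theta.standard_normal(alpha.size)
                psi_p = fp.psi(prop)
                E_p = G_cells @ (psi_p * eff)
                lp0l_p = fp.log_pi0lam(lam, E_p)
                ind_p = fp.ind_terms(Gc, d2c, psi_p, eff, prop, xi, sigma)
                delta = (n0 * lp0l_p + ind_p + prior_q(prop)) - (
                    n0 * lp0l + ind + prior_q(alpha)
                )
                if np.log(rng_theta.uniform()) < delta:
                    alpha, psi, E_cells, lp0l, ind = prop, psi_p, E_p, lp0l_p, ind_p
                    accepted = True
            elif block == "xi":
                prop = xi + s * rng_theta.standard_normal(q)
                eff_p = fp.effdur(prop)
                E_p = G_cells @ (psi * eff_p)
                lp0l_p = fp.log_pi0lam(lam, E_p)
                ind_p = fp.ind_terms(Gc, d2c, psi, eff_p, alpha, prop, sigma)
                delta = (n0 * lp0l_p + ind_p + prior_q(prop)) - (
                    n0 * lp0l + ind + prior_q(xi)
                )
                if np.log(rng_theta.uniform()) < delta:
                    xi, eff, E_cells, lp0l, ind = prop, eff_p, E_p, lp0l_p, ind_p
                    accepted = True
            else:  # sigma, random walk on log scale with Jacobian
                new_ls = np.log(sigma) + s * rng_theta.standard_normal()
                sig_p = float(np.exp(new_ls))
                u = rng_theta.uniform()
                if sig_p < sig_max:
                    Gcells_p = fp.cell_kernel(sig_p)
                    E_p = Gcells_p @ (psi * eff)
                    lp0l_p = fp.log_pi0lam(lam, E_p)
                    Gc_p = np.exp(-d2c / (2.0 * sig_p**2))
                    ind_p = fp.ind_terms(Gc_p, d2c, psi, eff, alpha, xi, sig_p)
                    delta = (n0 * lp0l_p + ind_p) - (n0 * lp0l + ind) + (
                        new_ls - np.log(sigma)
                    )
                    if np.log(u) < delta:
                        sigma, G_cells, E_cells, lp0l, Gc, ind = (
                            sig_p,
                            Gcells_p,
                            E_p,
                            lp0l_p,
                            Gc_p,
                            ind_p,
                        )
                        accepted = True
            acc_counts[block] += accepted
            acc_total[block] += 1
            if in_burn and config.adapt:
                rate = min(0.25, 5.0 / np.sqrt(it + 1.0))
                log_scales[block] += rate * ((1.0 if accepted else 0.0) - targets[block])

        # ---- centers -----------------------------------------------------
        if n:
            s = np.exp(log_scales["centers"])
            prop = centers + s * rng_centers.standard_normal((n, 2))
            unif = rng_centers.uniform(size=n)
            ok = domain.is_habitat(prop)
            prop_safe = np.where(ok[:, None], prop, centers)
            d2_p = np.sum(
                (prop_safe[:, None, :] - data.traps.locations[None, :, :]) ** 2, axis=2
            )
            G_p = np.exp(-d2_p / (2.0 * sigma**2))
            rate_vec = psi * eff
            cur_i = (
                (domain.covariates_at(centers) @ beta)
                - Gc @ rate_vec
                - (fp.y * d2c).sum(axis=1) / (2.0 * sigma**2)
            )
            prop_i = (
                (domain.covariates_at(prop_safe) @ beta)
                - G_p @ rate_vec
                - (fp.y * d2_p).sum(axis=1) / (2.0 * sigma**2)
            )
            accept = ok & (np.log(unif) < prop_i - cur_i)
            if accept.any():
                centers = centers.copy()
                centers[accept] = prop[accept]
                d2c[accept] = d2_p[accept]
                Gc[accept] = G_p[accept]
                ind = fp.ind_terms(Gc, d2c, psi, eff, alpha, xi, sigma)
                vcb = float((domain.covariates_at(centers) @ beta).sum())
            frac = float(accept.mean())
            acc_counts["centers"] += frac
            acc_total["centers"] += 1
            if in_burn and config.adapt:
                rate = min(0.25, 5.0 / np.sqrt(it + 1.0))
                log_scales["centers"] += rate * (frac - targets["centers"])

        # ---- n0 ----------------------------------------------------------
        n0 = int(rng_n0.poisson(np.exp(lp0l)))

        if not np.isfinite(ind + lp0l + Lam):
            raise RuntimeError(f"non-finite log-posterior at iteration {it}")

        if not in_burn:
            j = it - config.burn_in
            out_params[j] = np.concatenate([beta, alpha, xi, [sigma]])
            out_n0[j] = n0
            out_centers[j] = centers

    acceptance = {
        k: (acc_counts[k] / acc_total[k] if acc_total[k] else float("nan"))
        for k in acc_counts
    }
    return PosteriorChain(
        param_names=names,
        params=out_params,
        n0=out_n0,
        centers=out_centers,
        acceptance=acceptance,
        model=model,
        seed=config.seed,
        n_observed=n,
    )


def summarize_chain(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior mean, 2.5/97.5 percentiles and batch-means Monte Carlo SE.

    The MCSE uses ⌊√m⌋ batches of equal size.  Chains shorter than 10
    draws are refused.
    """
    m = len(chain)
    if m < 10:
        raise ValueError("chain too short to summarize (need >= 10 draws)")
    nb = int(np.sqrt(m))
    bsize = m // nb
    rows = {}
    for name in chain.param_names + ["n0"]:
        x = chain.column(name)
        trimmed = x[: nb * bsize].reshape(nb, bsize)
        bm = trimmed.mean(axis=1)
        mcse = float(bm.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
        rows[name] = {
            "mean": float(x.mean()),
            "2.5%": float(np.percentile(x, 2.5)),
            "97.5%": float(np.percentile(x, 97.5)),
            "mcse": mcse,
        }
    return pd.DataFrame(rows).T[["mean", "2.5%", "97.5%", "mcse"]]
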