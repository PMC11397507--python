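"""Three-level hierarchical Bayesian model (HBM) of the CSF.

The hierarchy is the standard three-level Gaussian chain on the log10
parameter vector θ = (log peakCS, log peakSF, log bandwidth):

    population:  μ ~ truncated-Normal (per parameter), Σ⁻¹ ~ Wishart
    individual:  ρ_i ~ N(μ, Σ),  φ⁻¹ ~ Wishart          (i = 1..I)
    test:        θ_ij ~ N(ρ_i, φ)                        (here J = 1)
    data:        r_ijk ~ Bernoulli(p(r=1 | θ_ij, sf, c))

Hyperprior means/SDs and the Wishart scales come from the first-stage BIP
fits: the truncated-normal hyperprior on each component of μ uses the
across-individual average of the BIP posterior means and SDs, truncated to
the parameter boxes; the Wishart priors on the precisions use the convention
W(Y, v) with *expected precision* Y and v = 4 degrees of freedom, so the
scale matrices are Σ_BIP⁻¹/v and φ_BIP⁻¹/v.

Posterior sampling is Metropolis-within-Gibbs: conditionally conjugate Gibbs
draws for ρ_i, μ (truncated via rejection) and the two precision matrices,
and an adaptive random-walk Metropolis step for each θ_i (step sizes tuned
toward 35% acceptance during the adaptation phase, then frozen).  Default
schedule: 3 chains x 2,000 retained draws (6,000 total) after 500,000
adaptation and 20,000 burn-in steps; reduced schedules are configuration.
Convergence is declared when every scalar parameter's Gelman–Rubin statistic
is below 1.05.

θ and μ are truncated to the parameter boxes; ρ_i is left untruncated (it is
a latent mean, not a CSF evaluated on data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .csf import (
    DEFAULT_CONSTANTS,
    LOG4LOG2,
    PARAM_BOUNDS,
    PARAM_NAMES,
    CSFParams,
    derive_attributes,
)
from .bip import BIPFit, BIPSummary
from .synth import INSTRUCTIONS, LOCATIONS

__all__ = [
    "HBMPriors",
    "HBMData",
    "MCMCConfig",
    "PosteriorSamples",
    "build_priors",
    "hbm_data_from_trials",
    "log_joint",
    "run_mcmc",
    "gelman_rubin",
    "final_estimates",
]


@dataclass(frozen=True)
class HBMPriors:
    """Hyperpriors assembled from the BIP population summaries."""

    mu_mean: np.ndarray  # (3,)
    mu_sd: np.ndarray  # (3,)
    mu_bounds: np.ndarray  # (3, 2) truncation boxes
    wishart_df: float  # v
    sigma_scale: np.ndarray  # (3,3): Σ_BIP⁻¹ / v
    phi_scale: np.ndarray  # (3,3): φ_BIP⁻¹ / v


def build_priors(summary: BIPSummary, wishart_df: float = 4.0) -> HBMPriors:
    """Priors per the two-stage recipe (BIP feeds the HBM)."""
    if np.any(summary.sigma0 <= 0):
        raise ValueError("sigma0 must be positive")
    return HBMPriors(
        mu_mean=np.asarray(summary.mu0, float),
        mu_sd=np.asarray(summary.sigma0, float),
        mu_bounds=PARAM_BOUNDS.copy(),
        wishart_df=float(wishart_df),
        sigma_scale=np.linalg.inv(summary.sigma_bip) / wishart_df,
        phi_scale=np.linalg.inv(summary.phi_bip) / wishart_df,
    )


@dataclass
class HBMData:
    """Per-individual trial data padded to a rectangular array (J = 1).

    ``labels`` holds one row per individual (participant, location,
    instruction) in the fixed fitting order.
    """

    log_sf: np.ndarray  # (I, Kmax)
    contrast: np.ndarray  # (I, Kmax)
    response: np.ndarray  # (I, Kmax) float 0/1
    mask: np.ndarray  # (I, Kmax) bool
    labels: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.log_sf.shape[0]


def hbm_data_from_trials(trials: pd.DataFrame, included_only: bool = True) -> HBMData:
    """Build HBM data from a trial table (columns participant, location,
    instruction, sf, contrast, response[, qc_status])."""
    df = trials
    if included_only and "qc_status" in df.columns:
        df = df[df["qc_status"] == "included"]
    loc_order = {l: i for i, l in enumerate(LOCATIONS)}
    ins_order = {s: i for i, s in enumerate(INSTRUCTIONS)}
    keys = sorted(
        df.groupby(["participant", "location", "instruction"]).groups.keys(),
        key=lambda k: (k[0], loc_order.get(k[1], 99), ins_order.get(k[2], 99)),
    )
    groups = df.groupby(["participant", "location", "instruction"])
    kmax = max(len(groups.get_group(k)) for k in keys)
    n = len(keys)
    log_sf = np.zeros((n, kmax))
    contrast = np.full((n, kmax), 0.5)
    response = np.zeros((n, kmax))
    mask = np.zeros((n, kmax), bool)
    rows = []
    for i, k in enumerate(keys):
        g = groups.get_group(k)
        m = len(g)
        log_sf[i, :m] = np.log10(g["sf"].to_numpy(float))
        contrast[i, :m] = g["contrast"].to_numpy(float)
        response[i, :m] = g["response"].to_numpy(float)
        mask[i, :m] = True
        rows.append({"participant": k[0], "location": k[1], "instruction": k[2], "n_trials": m})
    return HBMData(log_sf, contrast, response, mask, pd.DataFrame(rows))


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule; defaults follow the reported configuration."""

    n_chains: int = 3
    n_retained: int = 2000
    burn_in: int = 20_000
    adaptation: int = 500_000
    thin: int = 1
    target_accept: float = 0.35

    def reduced(self, adaptation: int = 1500, burn_in: int = 1500, thin: int = 5) -> "MCMCConfig":
        """A short smoke-run schedule retaining the same draw counts."""
        return MCMCConfig(
            n_chains=self.n_chains,
            n_retained=self.n_retained,
            burn_in=burn_in,
            adaptation=adaptation,
            thin=thin,
            target_accept=self.target_accept,
        )


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of every parameter and hyperparameter."""

    theta: np.ndarray  # (C, N, I, 3)
    rho: np.ndarray  # (C, N, I, 3)
    mu: np.ndarray  # (C, N, 3)
    sigma: np.ndarray  # (C, N, 3, 3) population covariance Σ
    phi: np.ndarray  # (C, N, 3, 3) individual covariance φ
    labels: pd.DataFrame
    config: MCMCConfig
    seed: int
    accept_rate: np.ndarray  # (C, I)
    converged: bool | None = None
    rhat: pd.Series | None = None

    @property
    def total_retained(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a (chains, draws) array, for diagnostics."""
        out: dict[str, np.ndarray] = {}
        n_ind = self.theta.shape[2]
        for i in range(n_ind):
            lab = self.labels.iloc[i]
            tag = f"{lab['participant']}_{lab['location']}_{lab['instruction']}"
            for k, name in enumerate(PARAM_NAMES):
                out[f"theta[{tag}].{name}"] = self.theta[:, :, i, k]
                out[f"rho[{tag}].{name}"] = self.rho[:, :, i, k]
        for k, name in enumerate(PARAM_NAMES):
            out[f"mu.{name}"] = self.mu[:, :, k]
        for a in range(3):
            for b in range(a, 3):
                out[f"Sigma[{a},{b}]"] = self.sigma[:, :, a, b]
                out[f"phi[{a},{b}]"] = self.phi[:, :, a, b]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table."""
        frames = []
        for name, arr in self.scalar_draws().items():
            c, n = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "draw": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _batched_loglik(theta: np.ndarray, data: HBMData, consts=DEFAULT_CONSTANTS) -> np.ndarray:
    """Bernoulli log likelihood per individual for θ of shape (I, 3)."""
    log_s = theta[:, 0:1] - LOG4LOG2 * (
        (data.log_sf - theta[:, 1:2]) / 10.0 ** theta[:, 2:3]
    ) ** 2
    cs = data.contrast * 10.0**log_s
    g, lam, beta = consts.guess_rate, consts.lapse_rate, consts.slope
    p1 = g + (1.0 - g - lam / 2.0) * (1.0 - np.exp(-(cs**beta)))
    p1 = np.clip(p1, 1e-12, 1.0 - 1e-12)
    ll = data.response * np.log(p1) + (1.0 - data.response) * np.log1p(-p1)
    return np.sum(ll * data.mask, axis=1)


def _in_box(x: np.ndarray) -> np.ndarray:
    """Boolean per row of (.., 3): inside the parameter truncation box."""
    lo, hi = PARAM_BOUNDS[:, 0], PARAM_BOUNDS[:, 1]
    return np.all((x >= lo) & (x <= hi), axis=-1)


def log_joint(
    theta: np.ndarray,
    rho: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    phi: np.ndarray,
    data: HBMData,
    priors: HBMPriors,
    consts=DEFAULT_CONSTANTS,
) -> float:
    """Unnormalised log joint density of the full HBM state.

    Sum of the Bernoulli log likelihood, the two Gaussian hierarchy layers,
    the truncated-normal hyperprior on μ and the Wishart log priors on the
    precisions; −inf when θ or μ leaves the truncation support.
    """
    theta = np.atleast_2d(theta)
    rho = np.atleast_2d(rho)
    if not (np.all(_in_box(theta)) and _in_box(mu)):
        return -np.inf
    total = float(np.sum(_batched_loglik(theta, data, consts)))
    total += float(
        sum(
            stats.multivariate_normal.logpdf(theta[i], rho[i], phi)
            for i in range(theta.shape[0])
        )
    )
    total += float(np.sum(stats.multivariate_normal.logpdf(rho, mu, sigma)))
    for k in range(3):
        lo, hi = priors.mu_bounds[k]
        a = (lo - priors.mu_mean[k]) / priors.mu_sd[k]
        b = (hi - priors.mu_mean[k]) / priors.mu_sd[k]
        total += float(
            stats.truncnorm.logpdf(mu[k], a, b, loc=priors.mu_mean[k], scale=priors.mu_sd[k])
        )
    total += float(
        stats.wishart.logpdf(np.linalg.inv(sigma), df=priors.wishart_df, scale=priors.sigma_scale)
    )
    total += float(
        stats.wishart.logpdf(np.linalg.inv(phi), df=priors.wishart_df, scale=priors.phi_scale)
    )
    return total


def _sample_truncated_mvn(
    mean: np.ndarray, chol_prec: np.ndarray, bounds: np.ndarray, rng, max_tries: int = 1000
) -> np.ndarray:
    """Rejection-sample a 3D normal (given precision Cholesky) inside a box."""
    for _ in range(max_tries):
        z = rng.standard_normal(3)
        x = mean + np.linalg.solve(chol_prec.T, z)
        if np.all(x >= bounds[:, 0]) and np.all(x <= bounds[:, 1]):
            return x
    return np.clip(mean, bounds[:, 0], bounds[:, 1])


def _run_chain(
    data: HBMData,
    priors: HBMPriors,
    config: MCMCConfig,
    rng: np.random.Generator,
    init_fits: list[BIPFit] | None,
    fix: dict,
    likelihood_on: bool,
):
    n_ind = data.n_individuals
    v = priors.wishart_df
    bounds = PARAM_BOUNDS

    # --- initial state (overdispersed across chains via rng jitter) ---
    if init_fits is not None:
        theta = np.stack([f.mean for f in init_fits])
        prop_cov = np.stack([f.cov + 1e-8 * np.eye(3) for f in init_fits])
    else:
        theta = np.tile(priors.mu_mean, (n_ind, 1))
        prop_cov = np.tile(np.diag(priors.mu_sd**2) + 1e-8 * np.eye(3), (n_ind, 1, 1))
    jitter_sd = np.sqrt(np.maximum(np.einsum("ikk->ik", prop_cov), 1e-8))
    theta = theta + rng.normal(0.0, jitter_sd)
    theta = np.clip(theta, bounds[:, 0] + 1e-9, bounds[:, 1] - 1e-9)
    rho = fix.get("rho", theta.copy())
    mu = fix.get("mu", np.clip(priors.mu_mean, bounds[:, 0], bounds[:, 1]))
    lam_sigma = (
        np.linalg.inv(fix["sigma"]) if "sigma" in fix else v * priors.sigma_scale
    )
    lam_phi = np.linalg.inv(fix["phi"]) if "phi" in fix else v * priors.phi_scale

    prop_chol = np.linalg.cholesky(prop_cov)
    log_step = np.full(n_ind, np.log(2.4 / np.sqrt(3.0)))
    prior_sigma_scale_inv = np.linalg.inv(priors.sigma_scale)
    prior_phi_scale_inv = np.linalg.inv(priors.phi_scale)
    mu_prior_prec = np.diag(1.0 / priors.mu_sd**2)

    def loglik(th):
        if not likelihood_on:
            return np.zeros(th.shape[0])
        return _batched_loglik(th, data)

    cur_ll = loglik(theta)

    def theta_logprior(th, rho_, lam_phi_):
        d = th - rho_
        quad = np.einsum("ij,jk,ik->i", d, lam_phi_, d)
        return -0.5 * quad  # normalization constant cancels in MH ratio

    cur_lp = theta_logprior(theta, rho, lam_phi)

    n_keep = config.n_retained
    theta_out = np.empty((n_keep, n_ind, 3))
    rho_out = np.empty((n_keep, n_ind, 3))
    mu_out = np.empty((n_keep, 3))
    sigma_out = np.empty((n_keep, 3, 3))
    phi_out = np.empty((n_keep, 3, 3))

    n_sampling = config.n_retained * config.thin
    total_sweeps = config.adaptation + config.burn_in + n_sampling
    accepts = np.zeros(n_ind)
    n_acc_sweeps = 0
    kept = 0

    for sweep in range(total_sweeps):
        adapting = sweep < config.adaptation
        sampling = sweep >= config.adaptation + config.burn_in

        # --- θ: batched random-walk Metropolis ---
        z = rng.standard_normal((n_ind, 3))
        prop = theta + np.exp(log_step)[:, None] * np.einsum("ijk,ik->ij", prop_chol, z)
        ok = _in_box(prop)
        prop_ll = np.where(ok, loglik(np.where(ok[:, None], prop, theta)), -np.inf)
        prop_lp = theta_logprior(prop, rho, lam_phi)
        log_ratio = (prop_ll + prop_lp) - (cur_ll + cur_lp)
        accept = ok & (np.log(rng.random(n_ind)) < log_ratio)
        theta = np.where(accept[:, None], prop, theta)
        cur_ll = np.where(accept, prop_ll, cur_ll)
        cur_lp = np.where(accept, prop_lp, cur_lp)
        if adapting:
            gamma = (sweep + 1) ** -0.6
            log_step += gamma * (accept.astype(float) - config.target_accept)
        else:
            accepts += accept
            n_acc_sweeps += 1

        # --- ρ_i: conjugate Gaussian ---
        if "rho" not in fix:
            a_prec = lam_sigma + lam_phi
            chol_a = np.linalg.cholesky(a_prec)
            b = (lam_sigma @ mu)[None, :] + theta @ lam_phi
            mean = np.linalg.solve(a_prec, b.T).T
            zr = rng.standard_normal((n_ind, 3))
            rho = mean + np.linalg.solve(chol_a.T, zr.T).T
            cur_lp = theta_logprior(theta, rho, lam_phi)

        # --- μ: conjugate Gaussian, truncated by rejection ---
        if "mu" not in fix:
            prec = mu_prior_prec + n_ind * lam_sigma
            b = mu_prior_prec @ priors.mu_mean + lam_sigma @ rho.sum(axis=0)
            mean = np.linalg.solve(prec, b)
            mu = _sample_truncated_mvn(mean, np.linalg.cholesky(prec), bounds, rng)

        # --- Σ⁻¹: conjugate Wishart ---
        if "sigma" not in fix:
            d = rho - mu
            scatter = d.T @ d
            scale = np.linalg.inv(prior_sigma_scale_inv + scatter)
            lam_sigma = stats.wishart.rvs(df=v + n_ind, scale=scale, random_state=rng)

        # --- φ⁻¹: conjugate Wishart ---
        if "phi" not in fix:
            d = theta - rho
            scatter = d.T @ d
            scale = np.linalg.inv(prior_phi_scale_inv + scatter)
            lam_phi = stats.wishart.rvs(df=v + n_ind, scale=scale, random_state=rng)
            cur_lp = theta_logprior(theta, rho, lam_phi)

        if sampling and (sweep - config.adaptation - config.burn_in) % config.thin == config.thin - 1:
            theta_out[kept] = theta
            rho_out[kept] = rho
            mu_out[kept] = mu
            sigma_out[kept] = np.linalg.inv(lam_sigma)
            phi_out[kept] = np.linalg.inv(lam_phi)
            kept += 1

    acc_rate = accepts / max(n_acc_sweeps, 1)
    return theta_out, rho_out, mu_out, sigma_out, phi_out, acc_rate


def run_mcmc(
    data: HBMData,
    priors: HBMPriors,
    config: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    init_fits: list[BIPFit] | None = None,
    fix: dict | None = None,
    likelihood_on: bool = True,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Sample the joint HBM posterior with independently seeded parallel chains.

    ``init_fits`` (per-individual BIP fits, in data order) seed the chain
    starts and the θ proposal covariances.  ``fix`` can pin any of
    ``{"mu", "rho", "sigma", "phi"}`` for validation runs;
    ``likelihood_on=False`` samples the prior (data ignored).  Non-convergence
    flags the result (``converged=False``) but never raises.
    """
    fix = fix or {}
    ss = np.random.SeedSequence(seed).spawn(config.n_chains)
    chains = [
        _run_chain(data, priors, config, np.random.default_rng(s), init_fits, fix, likelihood_on)
        for s in ss
    ]
    samples = PosteriorSamples(
        theta=np.stack([c[0] for c in chains]),
        rho=np.stack([c[1] for c in chains]),
        mu=np.stack([c[2] for c in chains]),
        sigma=np.stack([c[3] for c in chains]),
        phi=np.stack([c[4] for c in chains]),
        labels=data.labels.copy(),
        config=config,
        seed=seed,
        accept_rate=np.stack([c[5] for c in chains]),
    )
    if check_convergence and config.n_chains >= 2:
        samples.rhat = gelman_rubin(samples)
        samples.converged = bool((samples.rhat < 1.05).all())
    return samples


def gelman_rubin(samples) -> pd.Series:
    """Potential scale reduction factor per scalar parameter.

    Accepts a :class:`PosteriorSamples` or a mapping name -> (chains, draws)
    array.  Requires at least two chains.  Constant chains yield 1.0.
    """
    draws = samples.scalar_draws() if isinstance(samples, PosteriorSamples) else dict(samples)
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains of equal length")
        n = arr.shape[1]
        w = np.mean(np.var(arr, axis=1, ddof=1))
        b_over_n = np.var(np.mean(arr, axis=1), ddof=1)
        if w <= 0:
            out[name] = 1.0
            continue
        v_hat = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(v_hat / w))
    return pd.Series(out)


def final_estimates(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior-mean CSF per individual, with the five key attributes.

    The 6,000 pooled draws (all chains) of each individual's θ are averaged;
    the averaged parameters define that individual's final CSF from which
    cutoff-SF and AULCSF are computed.
    """
    pooled = samples.theta.reshape(-1, samples.theta.shape[2], 3).mean(axis=0)
    rows = []
    for i in range(pooled.shape[0]):
        lab = samples.labels.iloc[i]
        params = CSFParams(*np.clip(pooled[i], PARAM_BOUNDS[:, 0], PARAM_BOUNDS[:, 1]))
        attrs = derive_attributes(params)
        rows.append(
            {
                "participant": lab["participant"],
                "location": lab["location"],
                "instruction": lab["instruction"],
                "log_peak_cs": params.log_peak_cs,
                "log_peak_sf": params.log_peak_sf,
                "log_bandwidth": params.log_bandwidth,
                "peak_cs": attrs.peak_cs,
                "peak_sf": attrs.peak_sf,
                "bandwidth_fwhm": attrs.bandwidth_fwhm,
                "cutoff_sf": attrs.cutoff_sf,
                "aulcsf": attrs.aulcsf,
            }
        )
    return pd.DataFrame(rows)
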