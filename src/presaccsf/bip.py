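"""Bayesian inference procedure (BIP): independent grid-Bayes CSF fits.

The BIP scores each individual (one participant x location x instruction
unit, all of whose trials form a single test) independently: the posterior
over the CSF-parameter grid is proportional to the Bernoulli likelihood of
that individual's trials under a uniform prior whose support is the parameter
truncation box.  Its per-individual means, SDs and covariances seed the
hierarchical model's priors:

* ``mu0``/``sigma0`` — across-individual averages of the per-individual
  posterior means and SDs of each log10 parameter;
* ``Sigma_BIP`` — the between-individual covariance of the posterior means
  (population-level spread);
* ``phi_BIP`` — the average within-individual posterior covariance
  (individual-level measurement uncertainty).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csf import DEFAULT_CONSTANTS, LOG4LOG2, PsychometricConstants
from .qcsf import ParamGrid, PosteriorGrid

__all__ = ["BIPFit", "BIPSummary", "fit_bip", "bip_population_summaries"]


@dataclass(frozen=True)
class BIPFit:
    """Posterior summary for one individual's grid fit (log10 scale)."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,)
    cov: np.ndarray  # (3, 3)
    n_trials: int


@dataclass(frozen=True)
class BIPSummary:
    """Population-level summaries across all fitted individuals."""

    mu0: np.ndarray  # (3,) average posterior mean
    sigma0: np.ndarray  # (3,) average posterior SD
    sigma_bip: np.ndarray  # (3, 3) between-individual covariance of means
    phi_bip: np.ndarray  # (3, 3) mean within-individual covariance
    n_individuals: int

    def to_json(self, path) -> None:
        payload = {
            "mu0": self.mu0.tolist(),
            "sigma0": self.sigma0.tolist(),
            "sigma_bip": self.sigma_bip.tolist(),
            "phi_bip": self.phi_bip.tolist(),
            "n_individuals": self.n_individuals,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BIPSummary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mu0=np.array(d["mu0"]),
            sigma0=np.array(d["sigma0"]),
            sigma_bip=np.array(d["sigma_bip"]),
            phi_bip=np.array(d["phi_bip"]),
            n_individuals=int(d["n_individuals"]),
        )


def _grid_loglik(
    grid: ParamGrid, sf, contrast, response, consts: PsychometricConstants
) -> np.ndarray:
    """Summed log likelihood over trials for every grid cell.

    Trials are grouped by unique stimulus so the per-cell psychometric
    function is evaluated once per distinct (sf, contrast) pair.
    """
    stims = np.column_stack([sf, contrast])
    uniq, inverse = np.unique(stims, axis=0, return_inverse=True)
    n_corr = np.bincount(inverse, weights=np.asarray(response, float), minlength=len(uniq))
    n_tot = np.bincount(inverse, minlength=len(uniq)).astype(float)

    cells = grid.cells
    log_s = (
        cells[:, 0:1]
        - LOG4LOG2
        * ((np.log10(uniq[:, 0])[None, :] - cells[:, 1:2]) / 10.0 ** cells[:, 2:3]) ** 2
    )
    cs = uniq[:, 1][None, :] * 10.0**log_s
    g, lam, beta = consts.guess_rate, consts.lapse_rate, consts.slope
    p1 = g + (1.0 - g - lam / 2.0) * (1.0 - np.exp(-(cs**beta)))
    p1 = np.clip(p1, 1e-12, 1.0 - 1e-12)
    return np.log(p1) @ n_corr + np.log1p(-p1) @ (n_tot - n_corr)


def fit_bip(
    trials: pd.DataFrame,
    grid: ParamGrid | None = None,
    consts: PsychometricConstants = DEFAULT_CONSTANTS,
    return_posterior: bool = False,
):
    """Grid posterior for one individual's trials under a uniform prior.

    ``trials`` needs columns ``sf``, ``contrast``, ``response``.  With zero
    trials the posterior is the uniform prior (mean = grid midpoint).
    """
    grid = grid if grid is not None else ParamGrid.regular()
    sf = np.asarray(trials["sf"], dtype=float)
    if sf.size == 0:
        post = grid.uniform_prior()
    else:
        ll = _grid_loglik(
            grid, sf, np.asarray(trials["contrast"], float), trials["response"], consts
        )
        ll -= ll.max()
        w = np.exp(ll)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise FloatingPointError("degenerate BIP posterior (all-zero mass)")
        post = PosteriorGrid(grid, w)
    fit = BIPFit(mean=post.mean(), sd=post.sd(), cov=post.cov(), n_trials=int(sf.size))
    if return_posterior:
        return fit, post
    return fit


def _regularize(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Symmetrize; add eps*I until positive definite."""
    mat = (mat + mat.T) / 2.0
    jitter = eps
    for _ in range(12):
        try:
            np.linalg.cholesky(mat)
            return mat
        except np.linalg.LinAlgError:
            mat = mat + jitter * np.eye(mat.shape[0])
            jitter *= 10.0
    raise np.linalg.LinAlgError("could not regularize covariance matrix")


def bip_population_summaries(fits: list[BIPFit]) -> BIPSummary:
    """Assemble the population summaries that seed the HBM priors."""
    if len(fits) < 2:
        raise ValueError("need at least 2 individuals for a between-individual covariance")
    means = np.stack([f.mean for f in fits])
    sds = np.stack([f.sd for f in fits])
    covs = np.stack([f.cov for f in fits])
    sigma_bip = np.cov(means, rowvar=False, ddof=1)
    phi_bip = covs.mean(axis=0)
    return BIPSummary(
        mu0=means.mean(axis=0),
        sigma0=sds.mean(axis=0),
        sigma_bip=_regularize(sigma_bip),
        phi_bip=_regularize(phi_bip),
        n_individuals=len(fits),
    )
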