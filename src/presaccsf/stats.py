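"""Permutation-based repeated-measures statistics for the CSF attributes.

All p values follow the study's convention: permutation tests with (by
default) 1,000 shuffles, p = max(#{permuted statistic >= observed}, 1) / n,
so the achievable floor is exactly 1/n (0.001 at the default).  Repeated-
measures ANOVA F statistics come from the standard within-subject
decomposition (subject as blocking factor); the permutation null shuffles
condition labels within each participant — for a main effect, within the
strata of the other factor (exchangeable under that effect's null); for the
interaction, all cells within a participant are shuffled jointly.  Paired
comparisons use sign-flips of the paired differences.  Multiple comparisons
are corrected with Benjamini–Hochberg FDR.

Also here: the presaccadic-benefit curves (the ratio of contrast sensitivity
during saccade preparation and fixation, as a function of SF, with a
per-frequency one-way location ANOVA), and the flat-CSF likelihood-ratio
goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .csf import CSFParams, DEFAULT_CONSTANTS, log_likelihood, sensitivity

__all__ = [
    "TestResult",
    "perm_rm_anova",
    "perm_paired_t",
    "fdr_bh",
    "benefit_curve",
    "lrt_flat_null",
    "count_hbm_parameters",
]


@dataclass(frozen=True)
class TestResult:
    """One permutation test: statistic, permutation p, effect size."""

    effect: str
    statistic: float
    df: tuple
    p: float
    effect_size: float  # partial eta^2 for F tests, Cohen's d for t tests
    n_perm: int
    seed: int
    note: str = ""
    bf10: float | None = None  # reserved; not computed here


def _p_floor(count: int, n_perm: int) -> float:
    return max(count, 1) / n_perm


def _count_ge(null: np.ndarray, obs: float) -> int:
    """#{null >= obs}, counting numerical ties at the observed value."""
    tol = 1e-9 * max(1.0, abs(obs))
    return int(np.sum(np.asarray(null) >= obs - tol))


def _rm_anova_2way(y: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray, tuple]]:
    """Two-way within-subject F decomposition.

    ``y`` has shape (..., S, A, B); returns, per effect, (F, partial eta^2,
    (df_effect, df_error)) with any leading axes preserved.
    """
    s, a, b = y.shape[-3:]
    m = y.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = y.mean(axis=(-2, -1), keepdims=True)
    m_a = y.mean(axis=(-3, -1), keepdims=True)
    m_b = y.mean(axis=(-3, -2), keepdims=True)
    m_sa = y.mean(axis=-1, keepdims=True)
    m_sb = y.mean(axis=-2, keepdims=True)
    m_ab = y.mean(axis=-3, keepdims=True)

    ss_a = (s * b) * np.sum((m_a - m) ** 2, axis=(-3, -2, -1))
    ss_b = (s * a) * np.sum((m_b - m) ** 2, axis=(-3, -2, -1))
    ss_ab = s * np.sum((m_ab - m_a - m_b + m) ** 2, axis=(-3, -2, -1))
    ss_sa = b * np.sum((m_sa - m_s - m_a + m) ** 2, axis=(-3, -2, -1))
    ss_sb = a * np.sum((m_sb - m_s - m_b + m) ** 2, axis=(-3, -2, -1))
    ss_sab = np.sum(
        (y - m_sa - m_sb - m_ab + m_s + m_a + m_b - m) ** 2, axis=(-3, -2, -1)
    )

    def f_of(ss_eff, df_eff, ss_err, df_err):
        denom = ss_err / df_err
        f = np.where(ss_eff <= 0, 0.0, ss_eff / df_eff / np.where(denom > 0, denom, np.inf))
        f = np.where((ss_eff > 0) & (ss_err <= 0), np.inf, f)
        with np.errstate(invalid="ignore"):
            eta = np.where(ss_eff + ss_err > 0, ss_eff / (ss_eff + ss_err), 0.0)
        return f, eta

    out = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("A", ss_a, a - 1, ss_sa, (s - 1) * (a - 1)),
        ("B", ss_b, b - 1, ss_sb, (s - 1) * (b - 1)),
        ("AxB", ss_ab, (a - 1) * (b - 1), ss_sab, (s - 1) * (a - 1) * (b - 1)),
    ):
        f, eta = f_of(ss_eff, df_eff, ss_err, df_err)
        out[name] = (f, eta, (df_eff, df_err))
    return out


def _rm_anova_1way(y: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray, tuple]]:
    """One-way within-subject F; ``y`` has shape (..., S, A)."""
    s, a = y.shape[-2:]
    m = y.mean(axis=(-2, -1), keepdims=True)
    m_s = y.mean(axis=-1, keepdims=True)
    m_a = y.mean(axis=-2, keepdims=True)
    ss_a = s * np.sum((m_a - m) ** 2, axis=(-2, -1))
    ss_err = np.sum((y - m_s - m_a + m) ** 2, axis=(-2, -1))
    df_eff, df_err = a - 1, (s - 1) * (a - 1)
    denom = ss_err / df_err
    f = np.where(ss_a <= 0, 0.0, ss_a / df_eff / np.where(denom > 0, denom, np.inf))
    f = np.where((ss_a > 0) & (ss_err <= 0), np.inf, f)
    with np.errstate(invalid="ignore"):
        eta = np.where(ss_a + ss_err > 0, ss_a / (ss_a + ss_err), 0.0)
    return {"A": (f, eta, (df_eff, df_err))}


def _pivot(table: pd.DataFrame, dv: str, subject: str, within: list[str]) -> np.ndarray:
    """Balanced (S, A[, B]) array from a long table; raises if unbalanced."""
    pt = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if pt.isna().any().any():
        raise ValueError("unbalanced design: missing cells")
    levels = [sorted(table[w].unique()) for w in within]
    shape = (len(pt),) + tuple(len(l) for l in levels)
    counts = table.groupby([subject] + within).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")
    if len(within) == 1:
        pt = pt.reindex(columns=levels[0])
    else:
        pt = pt.reindex(columns=pd.MultiIndex.from_product(levels))
    return pt.to_numpy(float).reshape(shape)


def _permute_along(y: np.ndarray, axis: int, n_perm: int, rng) -> np.ndarray:
    """Stack n_perm independent shuffles of ``y`` along a new leading axis,
    permuting entries along ``axis`` independently within every other index."""
    rep = np.broadcast_to(y, (n_perm,) + y.shape).copy()
    keys = rng.random(rep.shape)
    order = np.argsort(keys, axis=axis + 1)
    return np.take_along_axis(rep, order, axis=axis + 1)


def perm_rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Permutation repeated-measures ANOVA with one or two within factors.

    Returns one :class:`TestResult` per effect, keyed by factor name (and
    ``"factor1 x factor2"`` for the interaction).
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    y = _pivot(table, dv, subject, within)
    rng = np.random.default_rng(seed)
    results: dict[str, TestResult] = {}

    if len(within) == 1:
        obs = _rm_anova_1way(y)["A"]
        perm = _permute_along(y, axis=1, n_perm=n_perm, rng=rng)
        f_null = _rm_anova_1way(perm)["A"][0]
        count = _count_ge(f_null, obs[0])
        results[within[0]] = TestResult(
            within[0], float(obs[0]), obs[2], _p_floor(count, n_perm), float(obs[1]), n_perm, seed
        )
        return results

    obs = _rm_anova_2way(y)
    schemes = {
        "A": (within[0], _permute_along(y, axis=1, n_perm=n_perm, rng=rng)),
        "B": (within[1], _permute_along(y, axis=2, n_perm=n_perm, rng=rng)),
    }
    # interaction: shuffle all cells jointly within each subject
    flat = _permute_along(y.reshape(y.shape[0], -1), axis=1, n_perm=n_perm, rng=rng)
    schemes["AxB"] = (f"{within[0]} x {within[1]}", flat.reshape((n_perm,) + y.shape))

    for key, (name, perm) in schemes.items():
        f_null = _rm_anova_2way(perm)[key][0]
        f_obs, eta, df = obs[key]
        count = _count_ge(f_null, f_obs)
        results[name] = TestResult(
            name, float(f_obs), df, _p_floor(count, n_perm), float(eta), n_perm, seed
        )
    return results


def perm_paired_t(
    x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0, effect: str = "paired"
) -> TestResult:
    """Paired t test with a sign-flip permutation null (two-sided on |t|).

    Cohen's d = mean(diff) / SD(diff).  All-zero differences give t = 0 and
    p = 1; zero-variance non-zero differences are flagged (t infinite).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    note = ""
    if sd == 0:
        if np.all(d == 0):
            return TestResult(effect, 0.0, (n - 1,), 1.0, 0.0, n_perm, seed, "all differences zero")
        t_obs, cohen, note = np.inf, np.inf, "zero-variance differences; t undefined"
    else:
        t_obs = d.mean() / (sd / np.sqrt(n))
        cohen = d.mean() / sd
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    dn = signs * d
    sd_n = dn.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(sd_n > 0, dn.mean(axis=1) / (sd_n / np.sqrt(n)), 0.0)
    count = _count_ge(np.abs(t_null), abs(t_obs))
    return TestResult(
        effect, float(t_obs), (n - 1,), _p_floor(count, n_perm), float(cohen), n_perm, seed, note
    )


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals.copy()
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return adj


def benefit_curve(
    estimates: pd.DataFrame,
    sf_grid: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Presaccadic benefit: S_saccade / S_fixation across spatial frequency.

    ``estimates`` is the final-estimate table (one row per participant,
    location, instruction with the log10 CSF parameters).  For each
    participant x location the fitted CSFs are evaluated on a dense log-spaced
    SF grid (default 51 points on 0.5–16 cpd) and the sensitivity ratio is
    formed; a one-way repeated-measures permutation ANOVA on location is run
    at every SF (on the log ratio, whose null of no location effect matches
    the ratio's).

    Returns a dict with ``curves`` (long DataFrame), ``location_tests``
    (per-SF ANOVA), and ``summary`` (per location: SF of the peak group-mean
    benefit and the group-mean fixation peak-SF).
    """
    if sf_grid is None:
        sf_grid = np.geomspace(0.5, 16.0, 51)
    locations = sorted(estimates["location"].unique())
    rows = []
    for (p, loc), g in estimates.groupby(["participant", "location"]):
        by_instr = {r["instruction"]: r for _, r in g.iterrows()}
        if not {"fixation", "saccade"} <= set(by_instr):
            raise ValueError(f"missing instruction for participant {p}, {loc}")
        pf = CSFParams(
            by_instr["fixation"]["log_peak_cs"],
            by_instr["fixation"]["log_peak_sf"],
            by_instr["fixation"]["log_bandwidth"],
        )
        ps = CSFParams(
            by_instr["saccade"]["log_peak_cs"],
            by_instr["saccade"]["log_peak_sf"],
            by_instr["saccade"]["log_bandwidth"],
        )
        ratio = sensitivity(ps, sf_grid) / sensitivity(pf, sf_grid)
        for f, r in zip(sf_grid, ratio):
            rows.append(
                {
                    "participant": p,
                    "location": loc,
                    "sf": f,
                    "benefit": r,
                    "fixation_peak_sf": pf.peak_sf,
                }
            )
    curves = pd.DataFrame(rows)

    tests = []
    for i, f in enumerate(sf_grid):
        sub = curves[np.isclose(curves["sf"], f)].copy()
        sub["log_benefit"] = np.log10(sub["benefit"])
        res = perm_rm_anova(
            sub, "log_benefit", ["location"], n_perm=n_perm, seed=seed + i
        )["location"]
        tests.append(
            {
                "sf": f,
                "F": res.statistic,
                "p": res.p,
                "eta_sq": res.effect_size,
                "n_perm": res.n_perm,
            }
        )
    location_tests = pd.DataFrame(tests)

    summary = []
    for loc in locations:
        sub = curves[curves["location"] == loc]
        mean_log = (
            sub.assign(lb=np.log10(sub["benefit"])).groupby("sf")["lb"].mean()
        )
        summary.append(
            {
                "location": loc,
                "peak_benefit_sf": float(mean_log.idxmax()),
                "peak_benefit": float(10.0 ** mean_log.max()),
                "fixation_peak_sf": float(sub.groupby("participant")["fixation_peak_sf"].first().mean()),
            }
        )
    return {"curves": curves, "location_tests": location_tests, "summary": pd.DataFrame(summary)}


def count_hbm_parameters(n_individuals: int) -> int:
    """Explicit HBM parameter count: θ and ρ (3 each per individual), μ (3),
    and the 6 free entries of each of Σ and φ."""
    return 6 * n_individuals + 15


def lrt_flat_null(
    trials: pd.DataFrame,
    estimates: pd.DataFrame,
    sf_levels: np.ndarray | None = None,
    consts=DEFAULT_CONSTANTS,
) -> dict:
    """Likelihood-ratio goodness-of-fit test against a flat-CSF null.

    The full model's log likelihood is evaluated at each individual's final
    CSF estimate; the null model gives each individual a constant sensitivity
    equal to the mean of that fitted CSF's sensitivity across the tested SF
    levels (one parameter per individual).  LR = 2(logL_full − logL_null) is
    referred to a chi-square with df = (counted full parameters) − I.
    """
    if sf_levels is None:
        sf_levels = np.geomspace(0.5, 16.0, 12)
    df_trials = trials
    if "qc_status" in trials.columns:
        df_trials = trials[trials["qc_status"] == "included"]
    g, lam, beta = consts.guess_rate, consts.lapse_rate, consts.slope
    ll_full = 0.0
    ll_null = 0.0
    n_ind = 0
    for (p, loc, instr), sub in df_trials.groupby(["participant", "location", "instruction"]):
        est = estimates[
            (estimates["participant"] == p)
            & (estimates["location"] == loc)
            & (estimates["instruction"] == instr)
        ]
        if est.empty:
            raise ValueError(f"no estimate for individual ({p}, {loc}, {instr})")
        row = est.iloc[0]
        params = CSFParams(row["log_peak_cs"], row["log_peak_sf"], row["log_bandwidth"])
        ll_full += log_likelihood(params, sub, consts)
        s_flat = float(np.mean(sensitivity(params, sf_levels)))
        c = sub["contrast"].to_numpy(float)
        r = sub["response"].to_numpy(float)
        p1 = g + (1.0 - g - lam / 2.0) * (1.0 - np.exp(-((c * s_flat) ** beta)))
        p1 = np.clip(p1, 1e-12, 1 - 1e-12)
        ll_null += float(np.sum(r * np.log(p1) + (1 - r) * np.log1p(-p1)))
        n_ind += 1
    lr = 2.0 * (ll_full - ll_null)
    df = count_hbm_parameters(n_ind) - n_ind
    return {
        "loglik_full": ll_full,
        "loglik_null": ll_null,
        "lr": lr,
        "df": df,
        "n_full_params": count_hbm_parameters(n_ind),
        "n_null_params": n_ind,
        "p": float(chi2.sf(max(lr, 0.0), df)),
    }
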