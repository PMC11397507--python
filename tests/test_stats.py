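"""Permutation tests, FDR, benefit curves, and the flat-CSF LRT."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from presaccsf.csf import CSFParams, log_likelihood, p_correct, sensitivity
from presaccsf.stats import (
    benefit_curve,
    count_hbm_parameters,
    fdr_bh,
    lrt_flat_null,
    perm_paired_t,
    perm_rm_anova,
)


def _design(n_subj=12, loc_effect=0.0, instr_effect=0.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        base = rng.normal(0, 1)
        for li, loc in enumerate(("upper", "lower", "horizontal")):
            for ii, instr in enumerate(("fixation", "saccade")):
                rows.append(
                    {
                        "participant": s,
                        "location": loc,
                        "instruction": instr,
                        "y": base + loc_effect * li + instr_effect * ii
                        + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


class TestPermRMANOVA:
    def test_floor_p_with_huge_effect(self):
        df = _design(instr_effect=50.0, noise=0.01, seed=1)
        res = perm_rm_anova(df, "y", ["location", "instruction"], n_perm=1000, seed=2)
        assert res["instruction"].p == 0.001

    def test_constant_dv_gives_zero_f_and_p_one(self):
        df = _design(noise=0.0, loc_effect=0.0, instr_effect=0.0, seed=3)
        df["y"] = 1.0
        res = perm_rm_anova(df, "y", ["location", "instruction"], n_perm=200, seed=4)
        for r in res.values():
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_observed_f_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = _design(loc_effect=0.5, instr_effect=0.4, noise=0.4, seed=5)
        res = perm_rm_anova(df, "y", ["location", "instruction"], n_perm=50, seed=6)
        ref = pingouin.rm_anova(
            data=df, dv="y", within=["location", "instruction"], subject="participant"
        )
        for effect, key in (
            ("location", "location"),
            ("instruction", "instruction"),
            ("location x instruction", "location * instruction"),
        ):
            f_ref = float(ref.loc[ref["Source"] == key, "F"].iloc[0])
            assert res[effect].statistic == pytest.approx(f_ref, rel=1e-9)

    def test_one_way_toy_matches_exhaustive_enumeration(self):
        # 3 participants x 2 levels: the sign-flip null is fully enumerable
        rows = []
        vals = {(0, "a"): 1.0, (0, "b"): 2.0, (1, "a"): 0.5, (1, "b"): 2.2, (2, "a"): 1.2, (2, "b"): 2.4}
        for (s, lev), v in vals.items():
            rows.append({"participant": s, "cond": lev, "y": v})
        df = pd.DataFrame(rows)

        # oracle: enumerate all within-subject label permutations
        y = np.array([[1.0, 2.0], [0.5, 2.2], [1.2, 2.4]])

        def f_stat(m):
            s, a = m.shape
            gm = m.mean()
            ss_a = s * ((m.mean(axis=0) - gm) ** 2).sum()
            resid = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0) + gm
            ss_e = (resid**2).sum()
            return (ss_a / (a - 1)) / (ss_e / ((s - 1) * (a - 1)))

        f_obs = f_stat(y)
        null = []
        for flips in itertools.product([False, True], repeat=3):
            m = y.copy()
            for i, fl in enumerate(flips):
                if fl:
                    m[i] = m[i, ::-1]
            null.append(f_stat(m))
        p_exact = max(sum(f >= f_obs - 1e-12 for f in null), 1) / len(null)

        res = perm_rm_anova(df, "y", ["cond"], n_perm=4000, seed=7)["cond"]
        assert res.statistic == pytest.approx(f_obs, rel=1e-9)
        assert res.p == pytest.approx(p_exact, abs=0.05)

    def test_unbalanced_design_rejected(self):
        df = _design(seed=8).iloc[:-1]
        with pytest.raises(ValueError):
            perm_rm_anova(df, "y", ["location", "instruction"], n_perm=10, seed=9)

    def test_type_one_error_calibrated(self):
        # no true effects: rejection rate at alpha=.05 must sit in the 99% CI
        n_rep = 200
        rejections = 0
        for rep in range(n_rep):
            df = _design(n_subj=8, seed=1000 + rep)
            res = perm_rm_anova(df, "y", ["location", "instruction"], n_perm=200, seed=rep)
            rejections += res["instruction"].p <= 0.05
        rate = rejections / n_rep
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= half


class TestPermPairedT:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        res = perm_paired_t(x, x, n_perm=100, seed=0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_exhaustive_sign_flip_n5(self):
        x = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
        y = np.array([1.0, 0.7, 1.1, 1.0, 0.6])
        d = x - y
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        # oracle: all 32 sign patterns
        null = []
        for signs in itertools.product([-1.0, 1.0], repeat=5):
            ds = d * np.array(signs)
            null.append(ds.mean() / (ds.std(ddof=1) / np.sqrt(5)))
        p_exact = max(sum(abs(t) >= abs(t_obs) - 1e-12 for t in null), 1) / len(null)
        res = perm_paired_t(x, y, n_perm=20000, seed=1)
        assert res.statistic == pytest.approx(t_obs, rel=1e-12)
        assert res.p == pytest.approx(p_exact, abs=0.02)

    def test_floor_with_large_separation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10.0, 0.1, 12)
        y = rng.normal(0.0, 0.1, 12)
        res = perm_paired_t(x, y, n_perm=1000, seed=3)
        assert res.p == 0.001

    def test_zero_variance_nonzero_mean_flagged(self):
        x = np.full(6, 2.0)
        y = np.zeros(6)
        res = perm_paired_t(x, y, n_perm=100, seed=4)
        assert math.isinf(res.statistic)
        assert res.note != ""

    def test_cohens_d(self):
        x = np.array([2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.5, 3.0, 4.5])
        d = x - y
        res = perm_paired_t(x, y, n_perm=100, seed=5)
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1))


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03]) == pytest.approx([0.03])

    def test_hand_formula(self):
        # oracle: p * m / rank with cumulative min from the largest rank
        got = fdr_bh([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])
        ps = np.array([0.001, 0.04, 0.03, 0.9])
        order = np.argsort(ps)
        m = len(ps)
        adj_sorted = ps[order] * m / (np.arange(m) + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(fdr_bh(ps), expected)

    def test_all_ones(self):
        assert np.allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(fdr_bh(ps)[perm], fdr_bh(ps[perm]))

    def test_empty(self):
        assert fdr_bh([]).size == 0


def _estimate_table(param_map):
    rows = []
    for (p, loc, instr), params in param_map.items():
        rows.append(
            {
                "participant": p,
                "location": loc,
                "instruction": instr,
                "log_peak_cs": params.log_peak_cs,
                "log_peak_sf": params.log_peak_sf,
                "log_bandwidth": params.log_bandwidth,
            }
        )
    return pd.DataFrame(rows)


class TestBenefitCurve:
    def _table(self, sacc_factor_cs=1.0, sacc_factor_sf=1.0):
        base = CSFParams.from_linear(40.0, 1.3, 2.0)
        table = {}
        for p in range(1, 4):
            for loc in ("upper", "lower", "horizontal"):
                table[(p, loc, "fixation")] = base
                table[(p, loc, "saccade")] = CSFParams.from_linear(
                    40.0 * sacc_factor_cs, 1.3 * sacc_factor_sf, 2.0
                )
        return _estimate_table(table)

    def test_identical_params_ratio_one(self):
        out = benefit_curve(self._table(), n_perm=20, seed=0)
        assert np.allclose(out["curves"]["benefit"], 1.0, atol=1e-12)

    def test_doubled_peak_cs_ratio_two_everywhere(self):
        out = benefit_curve(self._table(sacc_factor_cs=2.0), n_perm=20, seed=0)
        assert np.allclose(out["curves"]["benefit"], 2.0, rtol=1e-12)

    def test_sf_shift_peaks_above_fixation_peak(self):
        # oracle: the log-ratio of two log-parabolas with equal peakCS and
        # shifted peakSF is monotone increasing in log-sf, so the benefit
        # peaks above the fixation peak-SF
        out = benefit_curve(self._table(sacc_factor_sf=1.4), n_perm=20, seed=0)
        summary = out["summary"]
        assert (summary["peak_benefit_sf"] > summary["fixation_peak_sf"]).all()


class TestLRT:
    def _simulated(self, flat=False, seed=0):
        rng = np.random.default_rng(seed)
        params = CSFParams.from_linear(40.0, 1.3, 2.0)
        sf_levels = np.geomspace(0.5, 16.0, 12)
        rows = []
        s_flat = float(np.mean(sensitivity(params, sf_levels)))
        for p in (1, 2):
            for loc in ("upper",):
                for instr in ("fixation", "saccade"):
                    for _ in range(150):
                        sf = float(rng.choice(sf_levels))
                        c = float(np.exp(rng.uniform(np.log(0.005), 0.0)))
                        if flat:
                            drive = c * s_flat
                            p1 = 0.5 + 0.48 * (1 - np.exp(-(drive**2)))
                        else:
                            p1 = float(p_correct(params, sf, c))
                        rows.append(
                            {
                                "participant": p,
                                "location": loc,
                                "instruction": instr,
                                "sf": sf,
                                "contrast": c,
                                "response": int(rng.random() < p1),
                            }
                        )
        trials = pd.DataFrame(rows)
        est = _estimate_table(
            {
                (p, "upper", instr): params
                for p in (1, 2)
                for instr in ("fixation", "saccade")
            }
        )
        return trials, est

    def test_parameter_counts(self):
        assert count_hbm_parameters(72) == 447
        trials, est = self._simulated()
        out = lrt_flat_null(trials, est)
        assert out["n_null_params"] == 4
        assert out["df"] == count_hbm_parameters(4) - 4

    def test_curved_data_rejects_flat_null(self):
        trials, est = self._simulated(flat=False, seed=1)
        out = lrt_flat_null(trials, est)
        assert out["lr"] > 0
        assert out["loglik_full"] > out["loglik_null"]

    def test_flat_data_small_lr(self):
        # data generated from a truly flat observer: the curved model (fixed
        # at the log-parabola estimate) should not beat the flat null much
        lrs = []
        for seed in range(5):
            trials, est = self._simulated(flat=True, seed=seed)
            lrs.append(lrt_flat_null(trials, est)["lr"])
        assert np.median(lrs) < 0.0  # flat model fits flat data better
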