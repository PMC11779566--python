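import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rctbias import (
    ArmSummary,
    DegenerateEstimateError,
    InvalidInputError,
    Trial,
    fixed_effect_pool,
    mean_difference,
    risk_difference,
    summarize_arms,
)
from rctbias.meta_engine import arm_summaries_from_frame, arm_summaries_to_frame
from rctbias.trial_sim import assign_outcomes


def _trial_from_values(values_a, values_b):
    baseline = np.array(list(values_a) + list(values_b), dtype=float)
    return Trial(
        trial_id="t",
        subject_id=np.arange(1, len(baseline) + 1),
        arm=np.array(["A"] * len(values_a) + ["B"] * len(values_b)),
        baseline=baseline,
        outcome=assign_outcomes(baseline, 2.00),
        truth="unbiased",
    )


class TestSummarize:
    def test_hand_computed_mean_and_sd(self):
        a, b = summarize_arms(_trial_from_values([1, 2, 3], [1, 2, 3]))
        assert a.mean == pytest.approx(2.0) and a.sd == pytest.approx(1.0)
        assert a.n == 3

    def test_failure_counts(self):
        a, b = summarize_arms(_trial_from_values([1.5, 1.9], [2.5, 3.0]))
        assert a.failures == 0 and b.failures == 2

    def test_large_uniform_arm_mean(self, rng):
        v = rng.uniform(1.0, 4.5, 10_000)
        a, _ = summarize_arms(_trial_from_values(v, [1.0, 2.0]))
        assert abs(a.mean - 2.75) < 3 * (3.5 / math.sqrt(12)) / math.sqrt(10_000)

    def test_empty_arm_rejected(self):
        t = _trial_from_values([1.0, 2.0], [2.0, 3.0])
        broken = Trial(
            trial_id="t", subject_id=t.subject_id, arm=np.array(["A"] * 4),
            baseline=t.baseline, outcome=t.outcome, truth="unbiased",
        )
        with pytest.raises(InvalidInputError):
            summarize_arms(broken)


class TestEffectEstimates:
    def test_identical_arms_md(self):
        s = ArmSummary(n=100, mean=2.0, sd=1.0)
        est = mean_difference(s, s)
        assert est.point == 0.0 and est.p == pytest.approx(1.0)

    def test_md_closed_form(self):
        est = mean_difference(
            ArmSummary(n=100, mean=2.50, sd=1.00), ArmSummary(n=100, mean=2.75, sd=1.00)
        )
        assert est.point == pytest.approx(-0.25)
        assert est.se == pytest.approx(math.sqrt(0.02), rel=1e-12)
        assert est.z == pytest.approx(-1.7677670, abs=1e-6)
        assert est.p == pytest.approx(0.0770999, abs=1e-6)
        assert est.ci_low == pytest.approx(est.point - 1.959964 * est.se, abs=1e-5)

    def test_rd_closed_form(self):
        est = risk_difference(
            ArmSummary(n=100, mean=0, sd=1, failures=46),
            ArmSummary(n=100, mean=0, sd=1, failures=89),
        )
        assert est.point == pytest.approx(-0.43)
        assert est.se == pytest.approx(
            math.sqrt(0.46 * 0.54 / 100 + 0.89 * 0.11 / 100), rel=1e-12
        )

    def test_degenerate_estimates_raise(self):
        zero_sd = ArmSummary(n=100, mean=2.0, sd=0.0)
        with pytest.raises(DegenerateEstimateError):
            mean_difference(zero_sd, zero_sd)
        no_events = ArmSummary(n=100, mean=2.0, sd=1.0, failures=0)
        with pytest.raises(DegenerateEstimateError):
            risk_difference(no_events, no_events)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        na=st.integers(2, 500), nb=st.integers(2, 500),
        ma=st.floats(-10, 10), mb=st.floats(-10, 10),
        sa=st.floats(0.01, 5), sb=st.floats(0.01, 5),
        fa=st.floats(0.01, 0.99), fb=st.floats(0.01, 0.99),
    )
    def test_estimates_match_direct_arithmetic(self, na, nb, ma, mb, sa, sb, fa, fb):
        """MD/RD agree with brute-force formula evaluation to 12 significant digits."""
        xa = int(round(fa * na))
        xb = int(round(fb * nb))
        a = ArmSummary(n=na, mean=ma, sd=sa, failures=xa)
        b = ArmSummary(n=nb, mean=mb, sd=sb, failures=xb)
        md = mean_difference(a, b)
        assert md.point == pytest.approx(ma - mb, rel=1e-12, abs=1e-12)
        assert md.se == pytest.approx(
            math.sqrt(sa * sa / na + sb * sb / nb), rel=1e-12
        )
        ra, rb = xa / na, xb / nb
        se_rd = math.sqrt(ra * (1 - ra) / na + rb * (1 - rb) / nb)
        if se_rd > 0:
            rd = risk_difference(a, b)
            assert rd.point == pytest.approx(ra - rb, rel=1e-12, abs=1e-12)
            assert rd.se == pytest.approx(se_rd, rel=1e-12)


def _md(theta, se):
    # direct construction of an estimate with chosen point/se
    return mean_difference(
        ArmSummary(n=2, mean=theta, sd=se), ArmSummary(n=2, mean=0.0, sd=se)
    )


class TestPooling:
    def test_two_identical_estimates(self):
        e = _md(0.7, 1.0)
        res = fixed_effect_pool([e, e])
        assert res.pooled.point == pytest.approx(0.7)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.i2_percent == 0.0
        assert res.pooled.se == pytest.approx(e.se / math.sqrt(2), rel=1e-12)

    def test_hand_computed_q_and_i2(self):
        # theta {0, 2}, se {1, 1}: pooled 1, Q = 2, df = 1, I2 = 50%
        res = fixed_effect_pool([_md(0.0, 1.0), _md(2.0, 1.0)])
        assert res.pooled.point == pytest.approx(1.0)
        assert res.Q == pytest.approx(2.0)
        assert res.df == 1
        assert res.i2_percent == pytest.approx(50.0)

    def test_i2_truncated_at_zero(self):
        # theta {0, 1}, se {1, 1}: Q = 0.5 < df = 1
        res = fixed_effect_pool([_md(0.0, 1.0), _md(1.0, 1.0)])
        assert res.Q == pytest.approx(0.5)
        assert res.i2_percent == 0.0

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            fixed_effect_pool([_md(0.0, 1.0)])
        rd = risk_difference(
            ArmSummary(n=10, mean=0, sd=1, failures=5),
            ArmSummary(n=10, mean=0, sd=1, failures=3),
        )
        with pytest.raises(InvalidInputError):
            fixed_effect_pool([_md(0.0, 1.0), rd])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(0.05, 3)), min_size=2, max_size=8
        )
    )
    def test_pool_matches_brute_force_oracle(self, studies):
        """Pooled point/se, Q and I2 agree with direct weighted arithmetic."""
        ests = [_md(t, s) for t, s in studies]
        res = fixed_effect_pool(ests)
        w = [1.0 / e.se**2 for e in ests]
        pooled = sum(wi * e.point for wi, e in zip(w, ests)) / sum(w)
        Q = sum(wi * (e.point - pooled) ** 2 for wi, e in zip(w, ests))
        df = len(ests) - 1
        i2 = max(0.0, 100.0 * (Q - df) / Q) if Q > df else 0.0
        assert res.pooled.point == pytest.approx(pooled, rel=1e-12, abs=1e-12)
        assert res.pooled.se == pytest.approx(1 / math.sqrt(sum(w)), rel=1e-12)
        assert res.Q == pytest.approx(Q, rel=1e-10, abs=1e-12)
        assert res.i2_percent == pytest.approx(i2, rel=1e-10, abs=1e-12)
        assert 0.0 <= res.i2_percent <= 100.0
        assert (res.i2_percent == 0.0) == (res.Q <= res.df)
        # permutation invariance and information accrual
        rev = fixed_effect_pool(ests[::-1])
        assert rev.Q == pytest.approx(res.Q, rel=1e-10, abs=1e-12)
        assert res.pooled.se < min(e.se for e in ests)

    def test_matches_statsmodels_combine_effects(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        theta = rng.normal(0, 1, 6)
        se = rng.uniform(0.2, 1.5, 6)
        res = fixed_effect_pool([_md(t, s) for t, s in zip(theta, se)])
        sm = combine_effects(theta, se**2)
        assert res.pooled.point == pytest.approx(float(sm.mean_effect_fe), rel=1e-10)
        assert res.Q == pytest.approx(float(sm.q), rel=1e-10)
        assert res.i2_percent == pytest.approx(100 * float(sm.i2), rel=1e-8)

    def test_matches_r_metafor_fixed_effect(self, rng):
        theta = rng.normal(0, 1, 5).round(6)
        se = rng.uniform(0.3, 1.2, 5).round(6)
        res = fixed_effect_pool([_md(t, s) for t, s in zip(theta, se)])
        yi = ",".join(map(str, theta))
        sei = ",".join(map(str, se))
        code = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({yi}), sei=c({sei}), method='FE');"
            "cat(sprintf('%.12g %.12g %.12g %.12g', r$b[1], r$se, r$QE, r$I2))"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", "-e", code], capture_output=True, text=True, check=True
        )
        b, se_r, q_r, i2_r = map(float, out.stdout.split())
        assert res.pooled.point == pytest.approx(b, rel=1e-8)
        assert res.pooled.se == pytest.approx(se_r, rel=1e-8)
        assert res.Q == pytest.approx(q_r, rel=1e-8)
        assert res.i2_percent == pytest.approx(i2_r, rel=1e-6, abs=1e-8)


class TestCoverage:
    def test_md_ci_covers_null_at_nominal_rate(self):
        """95% CI on MD contains 0 for ~95% of identical-distribution arms."""
        rng = np.random.default_rng(99)
        n, sims = 100, 2000
        covered = 0
        for _ in range(sims):
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n)
            est = mean_difference(
                ArmSummary(n=n, mean=a.mean(), sd=a.std(ddof=1)),
                ArmSummary(n=n, mean=b.mean(), sd=b.std(ddof=1)),
            )
            covered += est.ci_low <= 0.0 <= est.ci_high
        rate = covered / sims
        band = 3 * math.sqrt(0.95 * 0.05 / sims)
        assert abs(rate - 0.95) < band + 0.005  # small allowance for z-vs-t at n=100


class TestArmSummaryIO:
    def test_csv_round_trip(self, tmp_path):
        rows = {
            "T1": (ArmSummary(100, 2.5, 1.0, 40), ArmSummary(100, 2.7, 0.9, 60)),
            "T2": (ArmSummary(50, 1.5, 0.5, 5), ArmSummary(50, 1.6, 0.6, 7)),
        }
        path = tmp_path / "arms.csv"
        arm_summaries_to_frame(rows).to_csv(path, index=False)
        import pandas as pd

        back = arm_summaries_from_frame(pd.read_csv(path))
        assert back == rows

    def test_missing_arm_rejected(self):
        import pandas as pd

        frame = pd.DataFrame(
            [{"trial_id": "T1", "arm": "A", "n": 10, "mean": 1.0, "sd": 0.5, "failures": 2}]
        )
        with pytest.raises(InvalidInputError):
            arm_summaries_from_frame(frame)
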