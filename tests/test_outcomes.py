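import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import oralmicro as om
from oralmicro.containers import ValidationError
from oralmicro.hazards import CoxModel, FineGrayModel

from conftest import make_meta


def sim_two_arm(n, log_hr, seed, censor=3.0, competing_rate=0.0):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t1 = rng.exponential(1.0 / np.exp(log_hr * x))
    rows = {"x": x}
    if competing_rate > 0:
        t2 = rng.exponential(1.0 / competing_rate, n)
        t = np.minimum(np.minimum(t1, t2), censor)
        ev = np.where(t == censor, 0, np.where(t1 <= t2, 1, 2))
    else:
        t = np.minimum(t1, censor)
        ev = (t1 <= censor).astype(int)
    rows.update({"time": t, "event": ev, "patient": [f"p{i}" for i in range(n)]})
    return pd.DataFrame(rows)


class TestClassifyRecovery:
    @staticmethod
    def _case(dist):
        meta = make_meta(
            [("s1", "p", "OM", "P", -10), ("s2", "p", "OM", "E30", 44)]
        )
        d = DistanceMatrix([[0, dist], [dist, 0]], ids=["s1", "s2"])
        return om.classify_recovery(d, meta)

    def test_threshold_is_strict(self):
        assert self._case(0.49).loc[0, "recovered"]
        assert not self._case(0.50).loc[0, "recovered"]

    def test_missing_e30_unevaluable(self):
        meta = make_meta([("s1", "p", "OM", "P", -10), ("s3", "p", "OM", "E", 14)])
        d = DistanceMatrix([[0, 0.2], [0.2, 0]], ids=["s1", "s3"])
        calls = om.classify_recovery(d, meta)
        assert not calls.loc[0, "evaluable"]
        assert calls.loc[0, "recovered"] is None

    def test_monotone_in_threshold(self, small_dm, small_bundle):
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            calls = om.classify_recovery(small_dm, small_bundle.meta, threshold=thr)
            rec = set(
                calls[calls.evaluable & calls.recovered.astype(bool)]
                .apply(lambda r: (r.patient, r.site), axis=1)
            )
            if prev is not None:
                assert prev <= rec
            prev = rec


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert om.spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert om.spearman(x, [30, 16, 9, 4, 2])[0] == pytest.approx(-1.0)

    def test_ties_average_ranks_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 3.0, 1.0, 5.0, 5.0, 2.0]

        def avg_ranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert om.spearman(x, y)[0] == pytest.approx(want)


class TestCox:
    def test_constant_covariate_hr_one(self):
        df = sim_two_arm(40, 0.0, seed=1)
        df["const"] = 1.0
        fit = om.cox_univariate(df, "const")
        assert fit.hr == pytest.approx(1.0)
        assert fit.p == 1.0

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        df = sim_two_arm(150, -0.7, seed=2)
        fit = om.cox_univariate(df, "x")
        ll = CoxPHFitter().fit(df[["time", "event", "x"]], "time", "event")
        assert fit.coef == pytest.approx(float(ll.params_.iloc[0]), abs=1e-5)
        se_ll = float(ll.standard_errors_.iloc[0])
        assert fit.se == pytest.approx(se_ll, rel=1e-3)

    def test_four_subject_grid_search_oracle(self):
        # tie-free, 1 covariate: maximize the explicit partial likelihood
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def pl(b):
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = time >= time[i]
                ll += b * x[i] - np.log(np.exp(b * x[risk]).sum())
            return ll

        grid = np.arange(-5, 5, 1e-3)
        b_star = grid[np.argmax([pl(b) for b in grid])]
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = CoxModel(df, ["x"]).fit()
        assert fit.params[0] == pytest.approx(b_star, abs=2e-3)

    def test_simulation_recovery(self):
        """Balanced two-arm exponential with true HR 0.2 and 300 subjects
        per arm: log HR recovered within +/-0.2 in >=90% of replicates."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_arm = 300
            x = np.repeat([0.0, 1.0], n_arm)
            t = rng.exponential(1 / np.exp(np.log(0.2) * x))
            df = pd.DataFrame(
                {
                    "time": t,
                    "event": np.ones(2 * n_arm, int),
                    "x": x,
                    "patient": [f"p{i}" for i in range(2 * n_arm)],
                }
            )
            fit = om.cox_univariate(df, "x")
            ok += abs(fit.coef - np.log(0.2)) <= 0.2
        assert ok >= 90

    def test_separation_flagged(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 0, 0, 0],
                "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            }
        )
        fit = om.cox_univariate(df, "x")
        assert fit.separation
        assert np.isfinite(fit.coef)

    def test_time_rescaling_invariance(self):
        df = sim_two_arm(120, -0.5, seed=3)
        f1 = om.cox_univariate(df, "x")
        df2 = df.assign(time=df["time"] * 2.7)
        f2 = om.cox_univariate(df2, "x")
        assert f1.coef == pytest.approx(f2.coef, abs=1e-10)


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        df = sim_two_arm(100, -0.6, seed=4)
        cox = om.cox_univariate(df, "x")
        fg = om.finegray_univariate(df, "x", event_of_interest=1)
        assert abs(fg.coef - cox.coef) < 1e-8
        assert "no competing events" in fg.note

    def test_matches_r_cmprsk(self, tmp_path):
        rng = np.random.default_rng(42)
        n = 120
        x = rng.binomial(1, 0.5, n).astype(float)
        t1 = rng.exponential(1 / (0.2 * np.exp(-0.8 * x)))
        t2 = rng.exponential(1 / 0.15, n)
        c = rng.uniform(1, 8, n)
        t = np.minimum(np.minimum(t1, t2), c)
        ev = np.where(t == c, 0, np.where(t1 <= t2, 1, 2))
        df = pd.DataFrame({"time": t, "event": ev, "x": x})
        fit = FineGrayModel(df, ["x"]).fit()
        csv = tmp_path / "fg.csv"
        df.to_csv(csv, index=False)
        rscript = (
            f'd<-read.csv("{csv}"); suppressMessages(library(cmprsk)); '
            "f<-crr(d$time, d$event, cov1=matrix(d$x), failcode=1, cencode=0); "
            'cat(sprintf("%.10f", f$coef))'
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        r_coef = float(out.stdout.strip())
        assert fit.params[0] == pytest.approx(r_coef, abs=1e-6)

    def test_subdistribution_simulation_recovery(self):
        """Data drawn from the subdistribution model itself (mixture
        construction with cause-1 probability 1-(1-p)^exp(bx)): the log
        sub-HR (true 0.25) is recovered within +/-0.25 in >=90% of
        replicates at n=400."""
        ok = 0
        true_log = np.log(0.25)
        p = 0.66
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 400
            x = np.repeat([0.0, 1.0], n // 2)
            eb = np.exp(true_log * x)
            p_x = 1 - (1 - p) ** eb
            cause1 = rng.random(n) < p_x
            # inverse transform on the conditional cause-1 subdistribution
            # F1(t|x)/p_x with baseline F(t) = p*(1-exp(-t))
            u = rng.random(n)
            inner = 1 - (1 - u * p_x) ** (1.0 / eb)
            t1 = -np.log(1 - np.clip(inner / p, 0, 1 - 1e-12))
            t = np.where(cause1, t1, rng.exponential(1.0, n))
            ev = np.where(cause1, 1, 2)
            cens = rng.uniform(2.0, 6.0, n)
            obs = np.minimum(t, cens)
            ev = np.where(t <= cens, ev, 0)
            df = pd.DataFrame({"time": obs, "event": ev, "x": x})
            fit = FineGrayModel(df, ["x"]).fit()
            ok += abs(fit.params[0] - true_log) <= 0.25
        assert ok >= int(np.ceil(0.9 * n_rep))

    def test_all_censored_flagged(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [0, 0, 0], "x": [0.0, 1.0, 0.5]}
        )
        fit = FineGrayModel(df, ["x"]).fit()
        assert not fit.converged
        assert not np.isfinite(fit.cov[0, 0])


class TestLandmark:
    def test_excludes_early_events(self):
        df = sim_two_arm(50, 0.0, seed=5)
        lm = 0.5
        recs, excluded = om.apply_landmark(df, lm)
        assert set(excluded) == set(df.loc[df.time < lm, "patient"])
        assert (recs["time"] >= lm).all()

    def test_per_patient_landmark_map(self):
        df = pd.DataFrame(
            {"patient": ["a", "b"], "time": [10.0, 50.0], "event": [1, 1], "x": [0, 1]}
        )
        recs, excluded = om.apply_landmark(df, {"a": 44.0, "b": 44.0})
        assert excluded == ["a"]
        with pytest.raises(ValidationError):
            om.apply_landmark(df, {"a": 44.0})


class TestMultivariate:
    def test_no_significant_confounders_equals_univariate(self):
        df = sim_two_arm(150, -0.8, seed=6)
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))
        joint, selected = om.multivariate_adjust(df, "x", ["noise"])
        assert selected == []
        uni = om.cox_univariate(df, "x")
        assert joint.fit_for("x").coef == pytest.approx(uni.coef, abs=1e-10)

    def test_threshold_one_admits_all(self):
        df = sim_two_arm(100, -0.5, seed=7)
        rng = np.random.default_rng(1)
        df["noise"] = rng.normal(size=len(df))
        _, selected = om.multivariate_adjust(df, "x", ["noise"], alpha=1.0)
        assert selected == ["noise"]

    def test_confounded_design_adjustment_helps(self):
        """Confounder drives both exposure and hazard; adjusting moves the
        primary estimate toward its true (null) direct effect."""
        rng = np.random.default_rng(8)
        n = 400
        z = rng.binomial(1, 0.5, n).astype(float)
        x = np.where(rng.random(n) < 0.8, z, 1 - z)  # x correlated with z
        t = rng.exponential(1.0 / np.exp(1.2 * z))  # hazard depends on z only
        c = np.minimum(t, 3.0)
        df = pd.DataFrame(
            {
                "patient": [f"p{i}" for i in range(n)],
                "time": np.minimum(t, 3.0),
                "event": (t <= 3.0).astype(int),
                "x": x,
                "z": z,
            }
        )
        unadjusted = om.cox_univariate(df, "x").coef
        joint, selected = om.multivariate_adjust(df, "x", ["z"])
        assert selected == ["z"]
        adjusted = joint.fit_for("x").coef
        assert abs(adjusted) < abs(unadjusted)

    def test_collinear_covariates_flagged(self):
        df = sim_two_arm(60, -0.5, seed=9)
        df["x2"] = df["x"] * 2.0
        with pytest.raises(ValidationError, match="collinear"):
            om.multivariate_adjust(df, "x", ["x2"], alpha=1.0)


class TestKmCif:
    def test_no_events_survival_one(self):
        df = pd.DataFrame(
            {"patient": list("abc"), "time": [1.0, 2.0, 3.0], "event": [0, 0, 0],
             "grp": ["g"] * 3}
        )
        curves = om.km_and_cif(df, "grp")
        assert (curves["g"]["km"]["survival"] == 1.0).all()

    def test_single_event_step(self):
        df = pd.DataFrame(
            {"patient": list("abcd"), "time": [1.0, 2.0, 3.0, 4.0],
             "event": [0, 1, 0, 0], "grp": ["g"] * 4}
        )
        km = om.km_and_cif(df, "grp")["g"]["km"]
        after = km.loc[km.time >= 2.0, "survival"].iloc[0]
        assert after == pytest.approx(1 - 1 / 3)  # 3 at risk at t=2

    def test_cif_sums_to_one_minus_km(self):
        df = sim_two_arm(150, -0.4, seed=10, competing_rate=0.3)
        curves = om.km_and_cif(df.assign(grp="g"), "grp")["g"]
        km = curves["km"].set_index("time")["survival"]
        for t in km.index[km.index > 0]:
            total_cif = 0.0
            for cause, cif in curves["cif"].items():
                sub = cif[cif.time <= t]
                total_cif += float(sub["cif"].iloc[-1]) if len(sub) else 0.0
            assert total_cif == pytest.approx(1 - km.loc[t], abs=1e-9)


class TestEndToEnd:
    def test_recovery_outcome_association_detected(self):
        """Cohorts with a 5x hazard for true non-recovery: the fitted HR for
        observed OM recovery is protective (HR<1, p<0.05) in most replicates."""
        detected = 0
        n_rep = 5
        for seed in range(n_rep):
            cfg = om.CohortConfig(n_patients=60, n_taxa=60, seed=100 + seed)
            b = om.generate_cohort(cfg)
            sub = b.meta[b.meta.site == "OM"]
            counts = b.counts.subset_samples(sub["sample_id"])
            dm = om.unifrac_distance_matrix(counts, b.tree)
            calls = om.classify_recovery(dm, sub)
            calls = calls[calls.evaluable]
            merged = b.outcomes.merge(
                calls[["patient", "recovered"]], on="patient"
            )
            merged["recovered"] = merged["recovered"].astype(bool).astype(int)
            lm = {p: 44.0 for p in merged["patient"]}
            fit = om.cox_univariate(merged, "recovered", landmark_days=lm)
            detected += (fit.hr < 1) and (fit.p < 0.05)
        assert detected >= int(0.8 * n_rep)
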