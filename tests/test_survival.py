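import numpy as np
import pandas as pd
import pytest

from orcasurv.survival import (
    CoxScaffold,
    build_person_periods,
    classify_salmon,
    classify_salmon_periods,
    describe_hazard_ratio,
    fit_binomial_glmm,
    fit_cox,
    hazard_ratio_interpretation,
)


class TestSalmonClassification:
    def test_lowest_quartile_of_twenty(self):
        s = classify_salmon(pd.DataFrame({"year": range(1991, 2011), "index": range(1, 21)}))
        assert (s.loc[s["index"] <= 5, "class"] == "low").all()
        assert (s.loc[s["index"] > 5, "class"] == "high").all()

    def test_eight_distinct_values_two_low(self):
        s = classify_salmon(pd.DataFrame({"year": range(8), "index": [3, 8, 1, 9, 5, 7, 6, 4]}))
        assert set(s.loc[s["class"] == "low", "index"]) == {1, 3}

    def test_all_equal_degenerates_to_high(self):
        with pytest.warns(UserWarning, match="all equal"):
            s = classify_salmon(pd.DataFrame({"year": range(5), "index": [2.0] * 5}))
        assert (s["class"] == "high").all()

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            classify_salmon(pd.DataFrame({"year": [1, 2, 3], "index": [1.0, 2.0, 3.0]}))

    def test_period_classes_respect_pooling(self):
        salmon = pd.DataFrame({"year": range(2000, 2008), "index": [1, 1, 9, 9, 9, 9, 9, 9]})
        mapping = {y: f"{2000 + 2 * ((y - 2000) // 2)}p" for y in range(2000, 2008)}
        classes = classify_salmon_periods(salmon, mapping)
        assert classes["2000p"] == "low"
        assert all(v == "high" for k, v in classes.items() if k != "2000p")


def _centrality_rows(rows):
    return pd.DataFrame(
        rows,
        columns=["period", "individual", "community", "community_size", "degree_norm",
                 "closeness_rank_norm"],
    )


class TestPersonPeriods:
    periods = [str(y) for y in range(1990, 1997)]
    starts = {p: float(i) for i, p in enumerate(periods)}
    stops = {p: float(i + 1) for i, p in enumerate(periods)}

    def _registry(self, fate="died", last="1995"):
        return pd.DataFrame(
            {
                "id": ["W1"],
                "sex": ["M"],
                "first_period": ["1990"],
                "last_period": [last],
                "fate": [fate],
            }
        )

    def test_event_lands_on_final_observed_row(self):
        cent = _centrality_rows(
            [(p, "W1", 0, 8, 0.5, 0.5) for p in self.periods if p <= "1995"]
        )
        t = build_person_periods(self._registry(), cent, self.starts, self.stops)
        assert t["event"].sum() == 1
        assert t.loc[t["event"] == 1, "period"].iloc[0] == "1995"
        assert (t["t_start"] < t["t_stop"]).all()

    def test_censored_whale_has_no_event(self):
        cent = _centrality_rows([(p, "W1", 0, 8, 0.5, 0.5) for p in self.periods])
        t = build_person_periods(
            self._registry(fate="censored", last="1996"), cent, self.starts, self.stops
        )
        assert t["event"].sum() == 0

    def test_small_community_period_dropped_others_kept(self):
        rows = [(p, "W1", 0, 8, 0.5, 0.5) for p in self.periods if p not in ("1993", "1995")]
        cent = _centrality_rows(rows)
        t = build_person_periods(self._registry(), cent, self.starts, self.stops)
        assert "1993" not in set(t["period"])
        # last observed row (1995) filtered away: the death cannot be placed
        assert t["event"].sum() == 0
        assert t.attrs["excluded_deaths"] == ["W1"]

    def test_entry_time_axis_left_truncates_at_first_row(self):
        cent = _centrality_rows([(p, "W1", 0, 8, 0.5, 0.5) for p in ("1992", "1993")])
        t = build_person_periods(
            self._registry(last="1993"), cent, self.starts, self.stops, time_axis="entry"
        )
        assert t["t_start"].iloc[0] == 0.0


def _exponential_person_periods(rng, n=400, beta=0.0, censor=4.0):
    x = rng.uniform(0, 1, n)
    rate = 0.3 * np.exp(beta * x)
    t = rng.exponential(1.0 / rate)
    event = (t <= censor).astype(int)
    t = np.minimum(t, censor)
    return pd.DataFrame(
        {
            "individual": [f"W{i}" for i in range(n)],
            "period": "p",
            "t_start": 0.0,
            "t_stop": t,
            "event": event,
            "sex": "M",
            "degree_norm": x,
            "closeness_rank_norm": x,
            "salmon_class": None,
            "community": 0,
            "community_size": n,
        }
    )


class TestCoxFit:
    def test_matches_lifelines(self):
        import warnings

        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(5)
        rows = []
        for i in range(150):
            t = 0
            for _ in range(6):
                xv = rng.uniform()
                died = rng.random() < 0.12
                rows.append((i, t, t + 1.0, int(died), xv))
                t += 1
                if died:
                    break
        df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x"])
        mine = CoxScaffold(df["start"], df["stop"], df["event"]).fit(df["x"].to_numpy())
        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(df, id_col="id", start_col="start", stop_col="stop",
                    event_col="event", formula="x")
        assert mine.coef == pytest.approx(float(ctv.params_["x"]), abs=1e-5)
        assert mine.se == pytest.approx(float(ctv.standard_errors_["x"]), abs=1e-5)

    def test_two_group_exponential_closed_form(self):
        rng = np.random.default_rng(6)
        n = 3000
        x = (rng.random(n) < 0.5).astype(float)
        rate = np.where(x > 0, 0.6, 0.3)  # log rate ratio = log 2
        t = rng.exponential(1.0 / rate)
        table = pd.DataFrame(
            {
                "t_start": 0.0,
                "t_stop": t,
                "event": 1,
                "sex": "M",
                "degree_norm": x,
                "salmon_class": None,
                "individual": "w",
                "period": "p",
                "closeness_rank_norm": x,
                "community": 0,
                "community_size": n,
            }
        )
        fit = fit_cox(table, "degree_norm")
        assert fit.coef == pytest.approx(np.log(2), abs=3 * fit.se)

    def test_null_covariate_hazard_ratio_near_one(self):
        rng = np.random.default_rng(7)
        fit = fit_cox(_exponential_person_periods(rng, n=500), "degree_norm")
        assert 0.75 < fit.hazard_ratio < 1.3

    def test_zero_events_is_informative_error(self):
        rng = np.random.default_rng(8)
        t = _exponential_person_periods(rng, n=20)
        t["event"] = 0
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(t, "degree_norm")

    def test_subsetting_by_sex_and_salmon(self):
        rng = np.random.default_rng(9)
        t = _exponential_person_periods(rng, n=300)
        t.loc[::2, "sex"] = "F"
        t["salmon_class"] = np.where(np.arange(len(t)) % 3 == 0, "low", "high")
        fit = fit_cox(t, "degree_norm", sex="F", salmon="low")
        sub = t[(t.sex == "F") & (t.salmon_class == "low")]
        assert fit.n_rows == len(sub)
        assert fit.n_events == int(sub.event.sum())

    def test_coverage_of_known_coefficient(self):
        rng = np.random.default_rng(10)
        true = np.log(0.5)
        hits = 0
        for _ in range(20):
            fit = fit_cox(_exponential_person_periods(rng, n=350, beta=true), "degree_norm")
            hits += abs(fit.coef - true) <= 2 * fit.se
        assert hits >= 16


class TestHazardRatioInterpretation:
    @pytest.mark.parametrize("hr, pct", [(0.25, -75.0), (1.0, 0.0), (2.0, 100.0)])
    def test_percent_change(self, hr, pct):
        assert hazard_ratio_interpretation(hr) == pytest.approx(pct)

    def test_quarter_reads_as_75_percent_decrease(self):
        assert describe_hazard_ratio(0.25) == (
            "75% decrease in the risk of mortality per unit of variable"
        )

    def test_monotone_in_coefficient(self):
        cs = np.linspace(-2, 2, 9)
        vals = [hazard_ratio_interpretation(np.exp(c)) for c in cs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hazard_ratio_interpretation(0.0)


def _glmm_data(rng, n_whales=60, n_periods=8, effect=0.0, sd_whale=0.7):
    rows = []
    intercepts = rng.normal(0, sd_whale, n_whales)
    for i in range(n_whales):
        for p in range(n_periods):
            low = p % 4 == 0
            logit = -0.3 + intercepts[i] + effect * low
            prob = 1 / (1 + np.exp(-logit))
            size = 9
            rows.append(
                {
                    "individual": f"W{i}",
                    "period": str(p),
                    "community": 0,
                    "community_size": size + 1,
                    "degree_raw": rng.binomial(size, prob),
                    "degree_norm": 0.0,
                    "closeness_rank_norm": 0.0,
                }
            )
    classes = {str(p): ("low" if p % 4 == 0 else "high") for p in range(n_periods)}
    return pd.DataFrame(rows), classes


class TestBinomialGlmm:
    def test_null_effect_recovered_near_zero(self):
        rng = np.random.default_rng(1)
        cent, classes = _glmm_data(rng)
        fit = fit_binomial_glmm(cent, classes)
        assert abs(fit.beta) < 0.25

    def test_positive_effect_sign_recovery(self):
        rng = np.random.default_rng(2)
        signs = 0
        for _ in range(10):
            cent, classes = _glmm_data(rng, effect=0.5)
            fit = fit_binomial_glmm(cent, classes)
            signs += fit.beta > 0
        assert signs >= 9

    def test_single_period_unidentifiable(self):
        rng = np.random.default_rng(3)
        cent, classes = _glmm_data(rng, n_periods=1)
        with pytest.raises(ValueError, match="random intercept"):
            fit_binomial_glmm(cent, classes)
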