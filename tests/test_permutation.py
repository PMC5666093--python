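import numpy as np
import pandas as pd
import pytest

from orcasurv.permutation import (
    DatastreamPermuter,
    counting_p_value,
    datastream_permutation,
    impute_sex_statistic,
    node_permutation,
    permutation_test,
)


@pytest.fixture
def person_periods():
    rows = []
    rng = np.random.default_rng(0)
    for p in ("1990", "1991"):
        for c, members in ((0, "ABC"), (1, "DEF")):
            for w in members:
                rows.append(
                    {
                        "individual": w,
                        "period": p,
                        "community": c,
                        "degree_norm": float(rng.integers(0, 10)) / 10,
                        "closeness_rank_norm": rng.random(),
                        "event": 0,
                        "sex": "M",
                        "t_start": 0.0,
                        "t_stop": 1.0,
                    }
                )
    return pd.DataFrame(rows)


class TestNodePermutation:
    def test_within_block_multisets_conserved(self, person_periods):
        rng = np.random.default_rng(1)
        out = node_permutation(person_periods, rng)
        for (p, c), block in person_periods.groupby(["period", "community"]):
            permuted = out[(out["period"] == p) & (out["community"] == c)]
            assert sorted(block["degree_norm"]) == sorted(permuted["degree_norm"])
            assert sorted(block["closeness_rank_norm"]) == sorted(
                permuted["closeness_rank_norm"]
            )

    def test_values_never_cross_communities(self, person_periods):
        # make community values disjoint so any crossing is visible
        pp = person_periods.copy()
        pp["degree_norm"] = np.where(pp["community"] == 0, pp["degree_norm"], 10 + pp["degree_norm"])
        rng = np.random.default_rng(2)
        for _ in range(50):
            out = node_permutation(pp, rng)
            assert (out.loc[out["community"] == 0, "degree_norm"] < 10).all()
            assert (out.loc[out["community"] == 1, "degree_norm"] >= 10).all()

    def test_non_covariate_columns_untouched(self, person_periods):
        out = node_permutation(person_periods, np.random.default_rng(3))
        pd.testing.assert_frame_equal(
            out.drop(columns=["degree_norm", "closeness_rank_norm"]),
            person_periods.drop(columns=["degree_norm", "closeness_rank_norm"]),
        )

    def test_seeded_determinism(self, person_periods):
        a = node_permutation(person_periods, np.random.default_rng(42))
        b = node_permutation(person_periods, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)


def _sightings(rows):
    return pd.DataFrame(rows, columns=["period", "encounter", "group", "individual"])


class TestDatastreamPermutation:
    def test_checkerboard_on_two_pairs(self):
        enc = _sightings(
            [
                ("P1", "E1", "G1", "A"),
                ("P1", "E1", "G1", "B"),
                ("P1", "E2", "G1", "C"),
                ("P1", "E2", "G1", "D"),
            ]
        )
        out = datastream_permutation(enc, "P1", n_swaps=1, rng=np.random.default_rng(0))
        groups = out.groupby(["encounter", "group"])["individual"].apply(set).tolist()
        assert groups != [{"A", "B"}, {"C", "D"}]
        assert all(len(g) == 2 for g in groups)
        assert sorted(out["individual"]) == ["A", "B", "C", "D"]

    def test_margins_exactly_preserved(self, toy_encounters):
        big = pd.concat(
            [toy_encounters, toy_encounters.assign(period="P2", encounter=lambda d: d.encounter + "x")]
        )
        permuter = DatastreamPermuter(big, burn_in=1000, spacing=0)
        out = permuter(None, np.random.default_rng(5))
        for df in (big, out):
            df = df.copy()
        for period in ("P1", "P2"):
            a = big[big["period"] == period]
            b = out[out["period"] == period]
            # per-individual sighting counts
            assert a.groupby("individual").size().to_dict() == b.groupby(
                "individual"
            ).size().to_dict()
            # group-size multiset and number of groups
            assert sorted(a.groupby(["encounter", "group"]).size()) == sorted(
                b.groupby(["encounter", "group"]).size()
            )

    def test_swaps_never_cross_periods(self, toy_encounters):
        other = toy_encounters.assign(period="P2", individual=lambda d: d.individual.str.lower(),
                                      encounter=lambda d: d.encounter + "x")
        big = pd.concat([toy_encounters, other])
        permuter = DatastreamPermuter(big, burn_in=500, spacing=0)
        out = permuter(None, np.random.default_rng(6))
        assert out.loc[out["period"] == "P1", "individual"].str.isupper().all()
        assert out.loc[out["period"] == "P2", "individual"].str.islower().all()

    def test_no_legal_swap_returns_input_with_warning(self):
        enc = _sightings([("P1", "E1", "G1", "A"), ("P1", "E1", "G1", "B")])
        permuter = DatastreamPermuter(enc, burn_in=10, spacing=0)
        with pytest.warns(UserWarning, match="no legal"):
            out = permuter(None, np.random.default_rng(7))
        pd.testing.assert_frame_equal(out, enc)

    def test_too_few_groups_rejected(self):
        enc = _sightings([("P1", "E1", "G1", "A")])
        with pytest.raises(ValueError, match="two groups"):
            datastream_permutation(enc, "P1", 10, np.random.default_rng(0))


class TestSexImputation:
    def test_no_unknowns_single_evaluation(self):
        reg = pd.DataFrame({"id": ["A", "B"], "sex": ["M", "F"]})
        calls = []

        def stat(r):
            calls.append(1)
            return 3.0

        assert impute_sex_statistic(stat, reg, n_imp=100) == 3.0
        assert len(calls) == 1

    def test_linear_statistic_matches_closed_form(self):
        reg = pd.DataFrame({"id": ["A", "B", "C"], "sex": ["M", "F", "U"]})

        def stat(r):  # 1 if the unknown whale drew male, else 0
            return float((r["sex"] == "M").sum() - 1)

        got = impute_sex_statistic(stat, reg, n_imp=1000, rng=np.random.default_rng(8))
        assert got == pytest.approx(0.5, abs=0.05)

    def test_seeded_reproducibility(self):
        reg = pd.DataFrame({"id": ["A", "B", "C"], "sex": ["U", "U", "F"]})

        def stat(r):
            return float((r["sex"] == "M").sum())

        a = impute_sex_statistic(stat, reg, n_imp=50, rng=np.random.default_rng(9))
        b = impute_sex_statistic(stat, reg, n_imp=50, rng=np.random.default_rng(9))
        assert a == b


class TestCountingRule:
    def test_worked_example(self):
        null = np.r_[np.full(49, 5.0), np.full(9950, -1.0)]
        assert counting_p_value(4.0, null, "ge") == pytest.approx(50 / 10000)

    def test_minimum_attainable(self):
        res = permutation_test(
            stat_fn=lambda d: float(np.sum(d)),
            permuter=lambda d, rng: rng.permutation(d) * 0.0,
            data=np.ones(5),
            n_perm=100,
            seed=0,
            direction="ge",
        )
        assert res.p_value == pytest.approx(1 / 101)

    def test_constant_statistic_gives_one(self):
        res = permutation_test(
            stat_fn=lambda d: 1.0,
            permuter=lambda d, rng: d,
            data=np.ones(3),
            n_perm=50,
            seed=1,
        )
        assert res.p_value == 1.0

    def test_bounds_property(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            m = int(rng.integers(1, 30))
            null = rng.normal(size=m)
            obs = rng.normal()
            for direction in ("ge", "le", "two_sided"):
                p = counting_p_value(obs, null, direction)
                assert 1 / (m + 1) <= p <= 1.0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(lambda d: 0.0, lambda d, r: d, None, n_perm=0)
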