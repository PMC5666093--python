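"""Null-model machinery: node and data-stream permutations, sex imputation,
and the permutation p-value counting rule.

Association data are autocorrelated, so model coefficients cannot be referred
to their asymptotic distributions.  Instead the observed test statistic is
compared with a null distribution built by refitting the model to permuted
data:

* **node permutation** — within each community and period, centrality values
  are reshuffled among the community's members; the network, survival
  outcomes and sex stay fixed.  This is the null for within-community
  analyses.
* **data-stream permutation** — checkerboard swaps of individuals between
  groups within a sampling period, preserving every whale's sighting count
  and every group's size exactly.  This is the null for population-level
  analyses.

The p-value follows the counting rule with the observed sample included in
numerator and denominator: p = (#{null vs observed} + 1) / (n_valid + 1), so
p is never below 1/(n_perm + 1) and never above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PermutationResult",
    "node_permutation",
    "datastream_permutation",
    "DatastreamPermuter",
    "impute_sex_statistic",
    "permutation_test",
]


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    n_perm: int
    p_value: float
    direction: str
    n_invalid: int = 0
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "observed_stat": float(self.observed_stat),
            "n_perm": int(self.n_perm),
            "n_invalid": int(self.n_invalid),
            "p_value": float(self.p_value),
            "direction": self.direction,
        }


def counting_p_value(observed: float, null_stats: np.ndarray, direction: str) -> float:
    """(b + 1)/(m + 1) with the observed sample counted on both sides."""
    null_stats = np.asarray(null_stats, dtype=float)
    m = len(null_stats)
    if direction == "ge":
        b = int(np.sum(null_stats >= observed))
    elif direction == "le":
        b = int(np.sum(null_stats <= observed))
    elif direction == "two_sided":
        b = int(np.sum(np.abs(null_stats) >= abs(observed)))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return (b + 1) / (m + 1)


def node_permutation(
    person_periods: pd.DataFrame,
    rng: np.random.Generator,
    covariates: tuple[str, ...] = ("degree_norm", "closeness_rank_norm"),
    group_cols: tuple[str, ...] = ("period", "community"),
) -> pd.DataFrame:
    """Reshuffle centrality values within each community and period.

    The permuted table has, within every (period, community) block, the same
    multiset of covariate values as the input; all other columns (events,
    sex, membership, intervals) are untouched.  Singleton blocks are identity.
    """
    out = person_periods.copy()
    cols = [c for c in covariates if c in out.columns]
    codes, _ = pd.factorize(
        pd.MultiIndex.from_frame(out[list(group_cols)].astype(str)), sort=False
    )
    order = np.argsort(codes, kind="stable")
    vals = out[cols].to_numpy()[order]
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.r_[0, boundaries]
    stops = np.r_[boundaries, len(sorted_codes)]
    for a, b in zip(starts, stops):
        perm = rng.permutation(b - a)
        vals[a:b] = vals[a:b][perm]
    unsort = np.empty_like(order)
    unsort[order] = np.arange(len(order))
    out[cols] = vals[unsort]
    return out


class DatastreamPermuter:
    """Stateful checkerboard-swap permuter of the group × individual incidence.

    Swaps pick individuals i, j and groups g, h within the same sampling
    period with i ∈ g, i ∉ h, j ∈ h, j ∉ g, and exchange the memberships.
    Per-individual sighting counts and group sizes are conserved exactly.
    Because consecutive swap states are correlated, the permuter burns in
    ``burn_in`` accepted swaps and spaces retained permutations ``spacing``
    accepted swaps apart.
    """

    def __init__(
        self,
        encounters: pd.DataFrame,
        periods: list[str] | None = None,
        burn_in: int = 1000,
        spacing: int = 100,
    ):
        self.table = encounters.copy().reset_index(drop=True)
        self.table["period"] = self.table["period"].astype(str)
        if periods is None:
            periods = sorted(self.table["period"].unique())
        self.periods = [str(p) for p in periods]
        self.rows_by_period = {
            p: self.table.index[self.table["period"] == p].to_numpy() for p in self.periods
        }
        # group key per row and membership sets per group for O(1) legality checks
        gkey = (
            self.table["period"]
            + "\x1f"
            + self.table["encounter"].astype(str)
            + "\x1f"
            + self.table["group"].astype(str)
        )
        self.row_group = gkey.to_numpy()
        self.row_ind = self.table["individual"].to_numpy().astype(object)
        self.members: dict[str, set] = {}
        for g, i in zip(self.row_group, self.row_ind):
            self.members.setdefault(g, set()).add(i)
        self.burn_in = burn_in
        self.spacing = spacing
        self._burned = False

    def _swap_once(self, rng: np.random.Generator, max_tries: int = 200) -> bool:
        period = self.periods[rng.integers(len(self.periods))] if len(self.periods) > 1 else self.periods[0]
        rows = self.rows_by_period[period]
        if len(rows) < 2:
            return False
        for _ in range(max_tries):
            r1, r2 = rng.integers(0, len(rows), size=2)
            a, b = rows[r1], rows[r2]
            g, h = self.row_group[a], self.row_group[b]
            i, j = self.row_ind[a], self.row_ind[b]
            if g == h or i == j:
                continue
            if i in self.members[h] or j in self.members[g]:
                continue
            self.members[g].discard(i)
            self.members[g].add(j)
            self.members[h].discard(j)
            self.members[h].add(i)
            self.row_ind[a], self.row_ind[b] = j, i
            return True
        return False

    def do_swaps(self, n_swaps: int, rng: np.random.Generator) -> int:
        done = 0
        for _ in range(n_swaps):
            if self._swap_once(rng):
                done += 1
        return done

    def __call__(self, _data, rng: np.random.Generator) -> pd.DataFrame:
        n = self.burn_in if not self._burned else self.spacing
        achieved = self.do_swaps(n, rng)
        if achieved == 0:
            import warnings

            warnings.warn("no legal checkerboard swap exists; returning input unchanged")
        self._burned = True
        out = self.table.copy()
        out["individual"] = self.row_ind.copy()
        return out


def datastream_permutation(
    encounters: pd.DataFrame,
    period: str,
    n_swaps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One-off data-stream permutation of a single period (n_swaps swaps)."""
    sub = encounters[encounters["period"].astype(str) == str(period)]
    if sub.groupby(["encounter", "group"]).ngroups < 2:
        raise ValueError("data-stream permutation needs at least two groups in the period")
    permuter = DatastreamPermuter(encounters, periods=[str(period)], burn_in=n_swaps, spacing=0)
    return permuter(None, rng)


def impute_sex_statistic(
    stat_fn,
    registry: pd.DataFrame,
    n_imp: int = 1000,
    rng: np.random.Generator | None = None,
    p_male: float = 0.5,
) -> float:
    """Average a statistic over random sex assignments for unknown-sex whales.

    Each of ``n_imp`` draws assigns every sex-U whale M or F independently
    (probability ``p_male`` of male, default 50:50) and evaluates
    ``stat_fn(registry_with_sexes)``; the mean over draws is returned.  With
    no unknown-sex whales the statistic is evaluated once.
    """
    unknown = registry.index[registry["sex"] == "U"]
    if len(unknown) == 0:
        return float(stat_fn(registry))
    rng = rng if rng is not None else np.random.default_rng()
    vals = []
    for _ in range(n_imp):
        imp = registry.copy()
        draws = np.where(rng.random(len(unknown)) < p_male, "M", "F")
        imp.loc[unknown, "sex"] = draws
        vals.append(stat_fn(imp))
    return float(np.mean(vals))


def permutation_test(
    stat_fn,
    permuter,
    data,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    direction: str = "auto",
) -> PermutationResult:
    """Generic permutation test with the counting-rule p-value.

    ``permuter(data, rng)`` must return a permuted copy of ``data``;
    ``stat_fn(data)`` maps a dataset to a real statistic.  ``direction`` is
    ``ge``/``le``/``two_sided``, or ``auto``: one-sided in the direction of
    the observed effect (ge if observed >= 0).  Null evaluations that fail or
    return NaN (e.g. non-convergent fits) are dropped from the denominator
    and counted in ``n_invalid``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(stat_fn(data))
    if direction == "auto":
        direction = "ge" if observed >= 0 else "le"
    null_stats = []
    n_invalid = 0
    for _ in range(n_perm):
        permuted = permuter(data, rng)
        try:
            val = float(stat_fn(permuted))
        except (ValueError, FloatingPointError):
            val = float("nan")
        if np.isnan(val):
            n_invalid += 1
        else:
            null_stats.append(val)
    null_stats = np.asarray(null_stats)
    p = counting_p_value(observed, null_stats, direction)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null_stats,
        n_perm=n_perm,
        p_value=p,
        direction=direction,
        n_invalid=n_invalid,
    )
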