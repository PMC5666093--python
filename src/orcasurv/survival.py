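"""Counting-process survival data and time-varying Cox proportional-hazards fits.

Whales enter the risk set at first observation (left truncation) and
contribute one (t_start, t_stop] interval per sampling period in which they
were observed and their community passed the size filter.  A whale with fate
"died" gets event = 1 on its final interval — death is detected by absence
the following summer, so the last measured social position naturally precedes
the death.  Salmon-stratified hazard ratios come from separate fits within
low/high strata, mirroring how per-stratum effects are reported.

The partial likelihood (Efron tie handling) for the single time-varying
covariate is maximised by an in-package Newton solver: permutation inference
refits the same model thousands of times with only the covariate changing,
so risk sets are precomputed once (:class:`CoxScaffold`) and each refit is a
few vectorised Newton steps.  The solver agrees with lifelines'
``CoxTimeVaryingFitter`` to optimizer precision (checked in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_salmon",
    "classify_salmon_periods",
    "build_person_periods",
    "CoxFit",
    "CoxScaffold",
    "fit_cox",
    "hazard_ratio_interpretation",
    "describe_hazard_ratio",
    "GlmmFit",
    "fit_binomial_glmm",
]

PERSON_PERIOD_COLUMNS = [
    "individual",
    "period",
    "t_start",
    "t_stop",
    "event",
    "sex",
    "degree_norm",
    "closeness_rank_norm",
    "salmon_class",
    "community",
    "community_size",
]


def classify_salmon(salmon: pd.DataFrame) -> pd.DataFrame:
    """Classify years into low/high salmon abundance by the lowest quartile.

    A year is "low" iff its index is at or below the first quartile (type-7
    sample quantile; ties at the threshold go to low), "high" otherwise.
    Requires at least 4 years.  An all-equal series has no lowest quartile:
    every year is classed high with a degeneracy warning.
    """
    salmon = salmon.copy()
    values = salmon["index"].to_numpy(dtype=float)
    if len(values) < 4:
        raise ValueError("salmon classification requires at least 4 years of data")
    if np.min(values) == np.max(values):
        warnings.warn("salmon indices are all equal; classifying every year as high")
        salmon["class"] = "high"
        return salmon
    q1 = float(np.quantile(values, 0.25))  # numpy 'linear' == type-7
    salmon["class"] = np.where(values <= q1, "low", "high")
    return salmon


def classify_salmon_periods(
    salmon: pd.DataFrame, year_to_period: dict[int, str]
) -> dict[str, str]:
    """Low/high class per sampling period.

    Each period's index is the mean of its member years' indices (years
    without data are skipped); the quartile rule is then applied to the
    period-level series, which reduces to the annual rule when nothing is
    pooled.  Periods with no salmon data at all get no class and are excluded
    from salmon-stratified analyses.
    """
    by_year = dict(zip(salmon["year"].astype(int), salmon["index"].astype(float)))
    accum: dict[str, list[float]] = {}
    for y, p in year_to_period.items():
        if y in by_year:
            accum.setdefault(p, []).append(by_year[y])
    if not accum:
        return {}
    frame = pd.DataFrame(
        {"year": range(len(accum)), "index": [float(np.mean(v)) for v in accum.values()]}
    )
    classed = classify_salmon(frame)
    return dict(zip(accum.keys(), classed["class"]))


def build_person_periods(
    registry: pd.DataFrame,
    centrality: pd.DataFrame,
    period_starts: dict[str, float],
    period_stops: dict[str, float],
    salmon_class: dict[str, str] | None = None,
    time_axis: str = "study",
) -> pd.DataFrame:
    """Assemble the counting-process person-period table.

    One row per whale per period with a centrality row (i.e. the whale was
    observed and its community passed the size filter).  ``event`` is 1 on the
    final row of a whale whose fate is "died", provided that final period
    survived the filter; otherwise the death is unplaceable and the whale is
    effectively censored (such exclusions are recorded in ``attrs``).

    ``time_axis`` — "study": intervals on the common study clock with entry
    left-truncated at first observation (keeps risk sets aligned with
    calendar periods, hence with salmon strata); "entry": time since the
    whale's own first included period.
    """
    if time_axis not in ("study", "entry"):
        raise ValueError("time_axis must be 'study' or 'entry'")
    cent = centrality.copy()
    cent["period"] = cent["period"].astype(str)
    sex = dict(zip(registry["id"], registry["sex"]))
    fate = dict(zip(registry["id"], registry["fate"]))
    rows = []
    excluded_deaths = []
    order = sorted(period_starts, key=period_starts.get)
    rank = {p: i for i, p in enumerate(order)}
    for ind, sub in cent.groupby("individual", sort=True):
        sub = sub.sort_values("period", key=lambda s: s.map(rank))
        offset = period_starts[sub["period"].iloc[0]] if time_axis == "entry" else 0.0
        last_period = sub["period"].iloc[-1]
        whale_died = fate.get(ind) == "died"
        last_observed = str(
            registry.loc[registry["id"] == ind, "last_period"].iloc[0]
        )
        for _, row in sub.iterrows():
            p = row["period"]
            event = int(whale_died and p == last_period and p == last_observed)
            rows.append(
                {
                    "individual": ind,
                    "period": p,
                    "t_start": period_starts[p] - offset,
                    "t_stop": period_stops[p] - offset,
                    "event": event,
                    "sex": sex.get(ind, "U"),
                    "degree_norm": row["degree_norm"],
                    "closeness_rank_norm": row["closeness_rank_norm"],
                    "salmon_class": (salmon_class or {}).get(p, None),
                    "community": row["community"],
                    "community_size": row["community_size"],
                }
            )
        if whale_died and last_period != last_observed:
            excluded_deaths.append(ind)
    table = pd.DataFrame(rows, columns=PERSON_PERIOD_COLUMNS)
    table.attrs["excluded_deaths"] = excluded_deaths
    return table


@dataclass
class CoxFit:
    """Single-covariate Cox partial-likelihood fit."""

    coef: float
    se: float
    n_events: int
    n_rows: int
    converged: bool = True

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))

    @property
    def z(self) -> float:
        return self.coef / self.se if self.se > 0 else float("nan")

    def as_dict(self) -> dict:
        return {
            "coef": self.coef,
            "hazard_ratio": self.hazard_ratio,
            "se": self.se,
            "z": self.z,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
            "converged": self.converged,
        }


class CoxScaffold:
    """Precomputed Efron risk/death sets for repeated single-covariate fits.

    Node permutations change only the covariate, never the intervals or
    events, so the risk-set structure is built once and each refit is a
    handful of vectorised Newton iterations.
    """

    def __init__(self, t_start, t_stop, event):
        t_start = np.asarray(t_start, dtype=float)
        t_stop = np.asarray(t_stop, dtype=float)
        event = np.asarray(event, dtype=int)
        if np.any(t_start >= t_stop):
            raise ValueError("person-period rows must satisfy t_start < t_stop")
        self.n_rows = len(t_stop)
        self.n_events = int(event.sum())
        self.blocks = []
        for t in np.unique(t_stop[event == 1]):
            risk = np.where((t_start < t) & (t_stop >= t))[0]
            death = np.where((t_stop == t) & (event == 1))[0]
            self.blocks.append((risk, death))

    def loglik(self, x: np.ndarray, beta: float) -> tuple[float, float, float]:
        """Efron log partial likelihood, gradient and Hessian at beta."""
        ll = grad = hess = 0.0
        eta = beta * x
        w = np.exp(eta)
        xw = x * w
        x2w = x * xw
        for risk, death in self.blocks:
            d = len(death)
            s_r, s_d = w[risk].sum(), w[death].sum()
            sx_r, sx_d = xw[risk].sum(), xw[death].sum()
            sx2_r, sx2_d = x2w[risk].sum(), x2w[death].sum()
            ll += eta[death].sum()
            frac = np.arange(d) / d
            denom = s_r - frac * s_d
            num1 = sx_r - frac * sx_d
            num2 = sx2_r - frac * sx2_d
            ll -= np.log(denom).sum()
            grad += x[death].sum() - (num1 / denom).sum()
            hess -= (num2 / denom - (num1 / denom) ** 2).sum()
        return ll, grad, hess

    def score_z(self, x: np.ndarray) -> float:
        """Efficient score statistic at beta = 0: U(0)/sqrt(I(0)).

        Asymptotically equivalent to the Wald z but defined even under
        monotone likelihood (separation), and needs no iteration — the
        preferred statistic for permutation refits.
        """
        x = np.asarray(x, dtype=float)
        _, grad, hess = self.loglik(x, 0.0)
        if hess >= 0:
            return float("nan")
        return float(grad / np.sqrt(-hess))

    def fit(self, x: np.ndarray, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
        x = np.asarray(x, dtype=float)
        if self.n_events == 0:
            raise ValueError("no events in the data; Cox fit is undefined")
        beta = 0.0
        converged = False
        for _ in range(max_iter):
            ll, grad, hess = self.loglik(x, beta)
            if not np.isfinite(ll) or hess >= 0:
                break
            step = -grad / hess
            step = float(np.clip(step, -2.0, 2.0))
            beta += step
            if abs(beta) > 25:  # monotone likelihood / separation
                break
            if abs(step) < tol:
                converged = True
                break
        _, _, hess = self.loglik(x, beta)
        se = float(np.sqrt(-1.0 / hess)) if hess < 0 else float("nan")
        if not np.isfinite(se):
            converged = False
        return CoxFit(
            coef=float(beta),
            se=se,
            n_events=self.n_events,
            n_rows=self.n_rows,
            converged=converged,
        )


def fit_cox(
    table: pd.DataFrame,
    covariate: str,
    sex: str | None = None,
    salmon: str | None = None,
) -> CoxFit:
    """Fit the extended Cox model for one covariate on a subset of the table.

    ``sex`` restricts rows to one sex; ``salmon`` in {"low", "high"} restricts
    to periods of that abundance class.  Raises if the subset has no events or
    no covariate variation; a fit stopped by monotone likelihood is returned
    with ``converged=False``.
    """
    sub = subset_person_periods(table, sex=sex, salmon=salmon)
    if sub.empty:
        raise ValueError("subset has no person-period rows")
    if int(sub["event"].sum()) == 0:
        raise ValueError("subset contains zero events; hazard ratio is not estimable")
    x = sub[covariate].to_numpy(dtype=float)
    if np.isnan(x).any():
        keep = ~np.isnan(x)
        sub, x = sub[keep], x[keep]
        if int(sub["event"].sum()) == 0:
            raise ValueError("all events lost to undefined covariate values")
    scaffold = CoxScaffold(sub["t_start"], sub["t_stop"], sub["event"])
    return scaffold.fit(x)


def subset_person_periods(table, sex=None, salmon=None) -> pd.DataFrame:
    sub = table
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    if salmon is not None:
        sub = sub[sub["salmon_class"] == salmon]
    return sub


def hazard_ratio_interpretation(hr: float) -> float:
    """Percent change in mortality risk per unit of the covariate.

    Returns 100·(hr − 1): e.g. a hazard ratio of 0.25 is a 75% decrease in
    risk per unit of the variable (negative return values are decreases).
    """
    if not hr > 0:
        raise ValueError("hazard ratio must be positive")
    return 100.0 * (hr - 1.0)


def describe_hazard_ratio(hr: float) -> str:
    pct = hazard_ratio_interpretation(hr)
    if pct == 0:
        return "0% change in risk of mortality per unit of variable"
    direction = "decrease" if pct < 0 else "increase"
    return f"{abs(pct):.4g}% {direction} in the risk of mortality per unit of variable"


@dataclass
class GlmmFit:
    beta: float
    se: float
    z: float
    intercept: float
    singular: bool = False


def fit_binomial_glmm(
    centrality: pd.DataFrame,
    salmon_class: dict[str, str],
    response: str = "degree_raw",
) -> GlmmFit:
    """Binomial GLMM of within-community degree on salmon class.

    Degree is modelled as ``degree_raw`` successes out of (community size − 1)
    trials against a low-salmon indicator, with a random intercept per whale
    (identity is the grouping factor).  Fitted by the variational-Bayes
    mixed-GLM routine in statsmodels; the fixed effect's posterior mean and
    sd give beta and z.
    """
    from scipy import sparse
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    cent = centrality.copy()
    cent["period"] = cent["period"].astype(str)
    cent["salmon_class"] = cent["period"].map(salmon_class)
    cent = cent.dropna(subset=["salmon_class"])
    per_whale = cent.groupby("individual")["period"].nunique()
    if (per_whale >= 2).sum() < 2:
        raise ValueError(
            "random intercept unidentifiable: need >= 2 whales observed in >= 2 periods"
        )
    successes = cent[response].to_numpy(dtype=int)
    trials = cent["community_size"].to_numpy(dtype=int) - 1
    low = (cent["salmon_class"] == "low").to_numpy(dtype=float)
    whale_codes, whales = pd.factorize(cent["individual"])
    # expand binomial trials to Bernoulli rows
    reps = trials
    endog = np.concatenate(
        [np.r_[np.ones(s), np.zeros(t - s)] for s, t in zip(successes, trials)]
    )
    row_of = np.repeat(np.arange(len(cent)), reps)
    exog = np.column_stack([np.ones(len(endog)), low[row_of]])
    exog_vc = sparse.csr_matrix(
        (np.ones(len(endog)), (np.arange(len(endog)), whale_codes[row_of])),
        shape=(len(endog), len(whales)),
    )
    ident = np.zeros(len(whales), dtype=int)
    model = BinomialBayesMixedGLM(
        endog, exog, exog_vc, ident, vcp_p=2.0, fe_p=2.0, fep_names=["intercept", "salmon_low"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit_vb()
    beta = float(fit.fe_mean[1])
    se = float(fit.fe_sd[1])
    singular = not np.isfinite(se) or se == 0
    z = beta / se if not singular else float("nan")
    return GlmmFit(beta=beta, se=se, z=z, intercept=float(fit.fe_mean[0]), singular=singular)
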