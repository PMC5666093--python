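"""Association networks from grouped sightings via the simple ratio index.

Under gambit-of-the-group sampling, every member of an observed group is
taken to be associating with every other member.  For a dyad (a, b) within
one sampling period the simple ratio index (SRI) is

    SRI = x / (x + y_ab + y_a + y_b)

where, counting over encounters (a whale belongs to at most one group per
encounter):

* ``x``    — encounters in which a and b were in the same group,
* ``y_ab`` — encounters in which both were seen but in different groups,
* ``y_a``  — encounters with a but not b (and symmetrically ``y_b``).

The denominator therefore equals the number of encounters in which either
whale was seen, and the SRI is the fraction of those sampling occasions on
which the two were grouped together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DyadCounts",
    "AssociationMatrix",
    "assign_sampling_periods",
    "period_order",
    "compute_sri",
    "aggregate_dyad_counts",
    "SocialDifferentiation",
    "estimate_social_differentiation",
]


@dataclass
class DyadCounts:
    """Symmetric dyadic count tables underlying one period's SRI matrix.

    ``x[i, j]`` counts encounters with i and j in the same group,
    ``together[i, j]`` counts encounters with both present (any group), and
    ``n_enc[i]`` counts encounters in which i was seen.  The remaining SRI
    components follow: ``y_ab = together - x``,
    ``y_a + y_b = n_i + n_j - 2·together``.
    """

    nodes: list
    x: np.ndarray
    together: np.ndarray
    n_enc: np.ndarray

    @property
    def y_ab(self) -> np.ndarray:
        return self.together - self.x

    def denominator(self) -> np.ndarray:
        """x + y_ab + y_a + y_b = encounters involving either member."""
        return self.n_enc[:, None] + self.n_enc[None, :] - self.together


@dataclass
class AssociationMatrix:
    """Simple-ratio association matrix for one sampling period.

    ``sampled[i, j]`` distinguishes dyads with at least one sampling
    opportunity (observed zero if weight 0) from never co-sampled dyads.
    """

    period: str
    nodes: list
    weights: np.ndarray
    counts: DyadCounts | None = None
    sampled: np.ndarray | None = None
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {n: i for i, n in enumerate(self.nodes)}
        if self.sampled is None:
            self.sampled = np.ones(self.weights.shape, dtype=bool)
            np.fill_diagonal(self.sampled, False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, a, b) -> float:
        return float(self.weights[self.index[a], self.index[b]])


def assign_sampling_periods(years, pooling=None) -> dict[int, str]:
    """Map each year to a sampling-period id.

    Parameters
    ----------
    years : iterable of int
        The years to assign (sorted internally).
    pooling : list of (start_year, end_year, width) or None
        Contiguous blocks and the number of years pooled per period within
        each block.  ``None`` pools nothing (one period per year).  Two-year
        pooling in the sparse early census — e.g. ``(1976, 1989, 2)`` — gives
        period ids like ``"1976-1977"``; width-1 periods are plain years.
    """
    years = sorted(int(y) for y in years)
    if pooling is None:
        pooling = [(years[0], years[-1], 1)] if years else []
    blocks = sorted(pooling)
    for (s1, e1, _), (s2, e2, _) in zip(blocks, blocks[1:]):
        if e1 >= s2:
            raise ValueError(f"overlapping pooling ranges: ({s1},{e1}) and ({s2},{e2})")
    mapping: dict[int, str] = {}
    for start, end, width in blocks:
        if width < 1:
            raise ValueError("pool width must be >= 1")
        for p0 in range(start, end + 1, width):
            p1 = min(p0 + width - 1, end)
            pid = str(p0) if p0 == p1 else f"{p0}-{p1}"
            for y in range(p0, p1 + 1):
                if y in mapping:
                    raise ValueError(f"year {y} assigned to two periods")
                if y in years:
                    mapping[y] = pid
    unassigned = [y for y in years if y not in mapping]
    if unassigned:
        raise ValueError(f"years outside every pooling block: {unassigned}")
    return mapping


def period_order(year_to_period: dict[int, str]) -> list[str]:
    """Period ids ordered by their earliest member year."""
    first: dict[str, int] = {}
    for y, p in year_to_period.items():
        first[p] = min(first.get(p, y), y)
    return sorted(first, key=first.get)


def period_bounds(year_to_period: dict[int, str]) -> dict[str, tuple[int, int]]:
    """Per period: (first member year, last member year + 1)."""
    bounds: dict[str, tuple[int, int]] = {}
    for y, p in year_to_period.items():
        lo, hi = bounds.get(p, (y, y + 1))
        bounds[p] = (min(lo, y), max(hi, y + 1))
    return bounds


def compute_sri(encounters: pd.DataFrame, period: str) -> AssociationMatrix:
    """Build the simple-ratio association matrix for one sampling period.

    Nodes are the individuals sighted at least once in the period.  Dyads
    never seen in a common encounter get weight 0 with ``sampled`` False.
    An empty period yields an empty matrix with a warning rather than an
    exception.
    """
    sub = encounters[encounters["period"].astype(str) == str(period)]
    if sub.empty:
        warnings.warn(f"period {period!r} has no encounters; returning empty matrix")
        empty = np.zeros((0, 0))
        return AssociationMatrix(
            period=str(period),
            nodes=[],
            weights=empty,
            counts=DyadCounts([], empty, empty, np.zeros(0)),
            sampled=empty.astype(bool),
        )
    nodes = sorted(sub["individual"].unique())
    ind = pd.Categorical(sub["individual"], categories=nodes).codes
    enc_key = sub["encounter"].astype(str)
    grp_key = enc_key + "\x1f" + sub["group"].astype(str)
    enc_codes, _ = pd.factorize(enc_key)
    grp_codes, _ = pd.factorize(grp_key)

    from scipy import sparse

    n = len(nodes)
    a_grp = sparse.csr_matrix(
        (np.ones(len(sub)), (ind, grp_codes)), shape=(n, grp_codes.max() + 1)
    )
    a_enc = sparse.csr_matrix(
        (np.ones(len(sub)), (ind, enc_codes)), shape=(n, enc_codes.max() + 1)
    )
    x = np.asarray((a_grp @ a_grp.T).todense())
    together = np.asarray((a_enc @ a_enc.T).todense())
    n_enc = np.diag(together).copy()
    np.fill_diagonal(x, 0)
    np.fill_diagonal(together, 0)
    counts = DyadCounts(nodes=nodes, x=x, together=together, n_enc=n_enc)
    denom = counts.denominator()
    np.fill_diagonal(denom, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(denom > 0, x / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(weights, 0.0)
    # a zero weight is an *observed* zero only if the dyad shared at least one
    # encounter; otherwise the dyad was never co-sampled directly
    sampled = counts.together > 0
    return AssociationMatrix(
        period=str(period), nodes=nodes, weights=weights, counts=counts, sampled=sampled
    )


def aggregate_dyad_counts(
    matrices, within_partition: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pool dyadic (joint, opportunity) counts across periods.

    Returns arrays ``k`` (joint-group counts) and ``n`` (sampling
    opportunities, the SRI denominator) over all dyads with n > 0, one entry
    per dyad per period.  With ``within_partition`` (individual -> community),
    only same-community dyads are pooled — the scale on which social
    differentiation is reported.
    """
    ks, ns = [], []
    for m in matrices:
        if m.counts is None or m.n_nodes < 2:
            continue
        denom = m.counts.denominator()
        iu = np.triu_indices(m.n_nodes, k=1)
        k = m.counts.x[iu]
        n = denom[iu]
        keep = n > 0
        if within_partition is not None:
            nodes = np.asarray(m.nodes)
            com = np.array([within_partition.get(v, -1) for v in nodes])
            same = (com[iu[0]] == com[iu[1]]) & (com[iu[0]] >= 0)
            keep &= same
        ks.append(k[keep])
        ns.append(n[keep])
    if not ks:
        return np.zeros(0), np.zeros(0)
    return np.concatenate(ks), np.concatenate(ns)


@dataclass
class SocialDifferentiation:
    """Likelihood estimate of association heterogeneity and sampling precision.

    ``S`` is the coefficient of variation of the latent (true) association
    indices under a beta-binomial model of the dyadic counts; ``r`` is the
    implied correlation between observed and true indices,
    r = sqrt(S²·H̄ / (1 + S²·H̄)) with H̄ the mean dyadic sample size.
    """

    S: float
    r: float
    mu: float
    mean_samples: float
    loglik: float
    degenerate: bool = False


def _betabinom_negll(params: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    logit_mu, log_nu = params
    mu = 1.0 / (1.0 + np.exp(-logit_mu))
    nu = np.exp(log_nu)
    a = mu * nu
    b = (1.0 - mu) * nu
    return -float(np.sum(stats.betabinom.logpmf(k, n, a, b)))


def estimate_social_differentiation(
    k: np.ndarray, n: np.ndarray, max_nu: float = 1e6
) -> SocialDifferentiation:
    """Fit the beta-binomial model to dyadic counts by maximum likelihood.

    Parameters
    ----------
    k, n : arrays
        Per dyad: joint-group count and number of sampling opportunities.

    Notes
    -----
    The latent association index of each dyad is modelled Beta(μν, (1−μ)ν);
    the observed joint count is binomial given the latent index.  S is the
    CV of that Beta: sqrt((1−μ) / (μ(ν+1))).  A fit driven to the ν bound
    (all dyads effectively identical) returns S ≈ 0 flagged degenerate.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    k, n = k[keep], n[keep]
    if len(k) < 2:
        raise ValueError("need at least two dyads with sampling opportunities")
    p_hat = float(np.sum(k) / np.sum(n))
    p_hat = min(max(p_hat, 1e-6), 1 - 1e-6)
    x0 = np.array([np.log(p_hat / (1 - p_hat)), 0.0])
    best = None
    for nu0 in (0.5, 5.0, 50.0):
        res = optimize.minimize(
            _betabinom_negll,
            np.array([x0[0], np.log(nu0)]),
            args=(k, n),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    logit_mu, log_nu = best.x
    mu = 1.0 / (1.0 + np.exp(-logit_mu))
    nu = float(np.exp(log_nu))
    degenerate = nu >= max_nu
    nu = min(nu, max_nu)
    s = float(np.sqrt((1.0 - mu) / (mu * (nu + 1.0))))
    if degenerate:
        s = 0.0
    h_bar = float(np.mean(n))
    r = float(np.sqrt(s**2 * h_bar / (1.0 + s**2 * h_bar)))
    return SocialDifferentiation(
        S=s, r=r, mu=float(mu), mean_samples=h_bar, loglik=-float(best.fun), degenerate=degenerate
    )
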