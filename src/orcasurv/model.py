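"""Model/Results interface tying the pipeline together.

:class:`SocialSurvivalModel` is built from the three data tables (grouped
sightings, individual registry, salmon series) or a synthetic configuration;
``fit()`` runs association networks → communities → within-community
centrality → counting-process survival, fits the per-sex and per-salmon-
stratum Cox models, and wraps each in its node-permutation null.  The
returned :class:`SocialSurvivalResults` carries estimates, permutation
p-values, network diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as oio
from .association import (
    aggregate_dyad_counts,
    compute_sri,
    estimate_social_differentiation,
)
from .centrality import CENTRALITY_COLUMNS, centrality_table
from .communities import detect_communities
from .permutation import PermutationResult, counting_p_value, node_permutation
from .survival import (
    CoxFit,
    CoxScaffold,
    build_person_periods,
    classify_salmon_periods,
    fit_cox,
    subset_person_periods,
)

__all__ = ["SocialSurvivalModel", "SocialSurvivalResults", "permutation_cox_test"]

_PERIOD_RE = re.compile(r"^(\d{4})(?:-(\d{4}))?$")


def bounds_from_period_ids(period_ids) -> dict[str, tuple[int, int]]:
    """(start year, stop year) per period id like ``"1996"`` or ``"1976-1977"``.

    Non-year ids fall back to unit-width slots in lexicographic order.
    """
    ids = sorted(set(str(p) for p in period_ids))
    parsed = {}
    for p in ids:
        m = _PERIOD_RE.match(p)
        if not m:
            parsed = None
            break
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        parsed[p] = (lo, hi + 1)
    if parsed is None:
        return {p: (i, i + 1) for i, p in enumerate(ids)}
    return parsed


def _cox_z(
    table: pd.DataFrame,
    covariate: str,
    sex: str | None,
    salmon: str | None,
    statistic: str = "score",
) -> float:
    """z statistic of one single-covariate Cox fit on a subset of the table."""
    sub = subset_person_periods(table, sex=sex, salmon=salmon)
    x = sub[covariate].to_numpy(dtype=float)
    ok = ~np.isnan(x)
    sub, x = sub[ok], x[ok]
    if sub.empty or int(sub["event"].sum()) == 0:
        raise ValueError("subset has no events; z statistic undefined")
    scaffold = CoxScaffold(sub["t_start"], sub["t_stop"], sub["event"])
    if statistic == "score":
        return scaffold.score_z(x)
    fit = scaffold.fit(x)
    return fit.z if fit.converged else float("nan")


def _imputed_cox_z(
    table: pd.DataFrame,
    registry: pd.DataFrame,
    covariate: str,
    sex: str | None,
    salmon: str | None,
    n_imp: int,
    rng: np.random.Generator,
    p_male: float = 0.5,
    statistic: str = "score",
) -> float:
    """Cox z on a subset, averaged over sex imputations for unknown-sex whales."""
    u_ids = set(registry.loc[registry["sex"] == "U", "id"]) & set(table["individual"])
    if sex is None or not u_ids:
        return _cox_z(table, covariate, sex, salmon, statistic)
    zs = []
    in_u = table["individual"].isin(u_ids).to_numpy()
    u_of_row = table.loc[in_u, "individual"].to_numpy()
    u_list = sorted(u_ids)
    u_index = {u: i for i, u in enumerate(u_list)}
    for _ in range(n_imp):
        draw = np.where(rng.random(len(u_list)) < p_male, "M", "F")
        imp = table.copy()
        imp.loc[in_u, "sex"] = [draw[u_index[u]] for u in u_of_row]
        try:
            zs.append(_cox_z(imp, covariate, sex, salmon, statistic))
        except ValueError:
            zs.append(np.nan)
    return float(np.nanmean(zs)) if not np.all(np.isnan(zs)) else float("nan")


def permutation_cox_test(
    person_periods: pd.DataFrame,
    registry: pd.DataFrame,
    covariate: str,
    sex: str | None = None,
    salmon: str | None = None,
    n_perm: int = 10000,
    n_imp: int = 1000,
    seed: int | np.random.Generator | None = None,
    direction: str = "auto",
    statistic: str = "score",
) -> PermutationResult:
    """Node-permutation null for one Cox model.

    The statistic compared across permutations is a model z statistic (the
    standard error changes under permutation, so the raw coefficient is not
    comparable): by default the efficient score z, which stays defined under
    monotone likelihood; ``statistic="wald"`` uses the Wald z from the full
    fit instead.  Centrality values are reshuffled within community × period;
    unknown-sex whales are re-imputed ``n_imp`` times per permutation and the
    mean z used.  Without unknown-sex whales the subset's risk sets are fixed
    across permutations, so refits reuse a precomputed scaffold.
    """
    if statistic not in ("score", "wald"):
        raise ValueError("statistic must be 'score' or 'wald'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = person_periods.reset_index(drop=True)
    u_present = bool(
        set(registry.loc[registry["sex"] == "U", "id"]) & set(table["individual"])
    ) and sex is not None

    null_stats = []
    n_invalid = 0
    if u_present:
        def stat(tab):
            return _imputed_cox_z(
                tab, registry, covariate, sex, salmon, n_imp, rng, statistic=statistic
            )

        observed = float(stat(table))
        if direction == "auto":
            direction = "ge" if observed >= 0 else "le"
        for _ in range(n_perm):
            permuted = node_permutation(table, rng, covariates=(covariate,))
            try:
                val = float(stat(permuted))
            except (ValueError, FloatingPointError):
                val = float("nan")
            if np.isnan(val):
                n_invalid += 1
            else:
                null_stats.append(val)
    else:
        # covariate-only permutation: the risk-set structure of the subset is
        # fixed, so shuffle the covariate vector in place of copying tables
        sub_idx = subset_person_periods(table, sex=sex, salmon=salmon).index.to_numpy()
        x_full = table[covariate].to_numpy(dtype=float)
        t_start = table["t_start"].to_numpy(dtype=float)[sub_idx]
        t_stop = table["t_stop"].to_numpy(dtype=float)[sub_idx]
        event = table["event"].to_numpy(dtype=int)[sub_idx]
        codes, _ = pd.factorize(
            pd.MultiIndex.from_frame(table[["period", "community"]].astype(str)), sort=False
        )
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        cuts = np.flatnonzero(np.diff(sorted_codes)) + 1
        blocks = [b for b in np.split(order, cuts) if len(b) > 1]
        scaffold_cache: dict[bytes, CoxScaffold] = {}

        def eval_x(xv: np.ndarray) -> float:
            x = xv[sub_idx]
            ok = ~np.isnan(x)
            key = ok.tobytes()
            if key not in scaffold_cache:
                if int(event[ok].sum()) == 0:
                    raise ValueError("no events after dropping undefined covariates")
                scaffold_cache[key] = CoxScaffold(t_start[ok], t_stop[ok], event[ok])
            if statistic == "score":
                return scaffold_cache[key].score_z(x[ok])
            fitres = scaffold_cache[key].fit(x[ok])
            return fitres.z if fitres.converged else float("nan")

        observed = float(eval_x(x_full))
        if direction == "auto":
            direction = "ge" if observed >= 0 else "le"
        for _ in range(n_perm):
            xp = x_full.copy()
            for blk in blocks:
                xp[blk] = xp[blk][rng.permutation(len(blk))]
            try:
                val = float(eval_x(xp))
            except (ValueError, FloatingPointError):
                val = float("nan")
            if np.isnan(val):
                n_invalid += 1
            else:
                null_stats.append(val)
    null_stats = np.asarray(null_stats, dtype=float)
    if np.isnan(observed):
        raise ValueError("observed Cox fit did not converge; permutation p undefined")
    p = counting_p_value(observed, null_stats, direction)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null_stats,
        n_perm=n_perm,
        p_value=p,
        direction=direction,
        n_invalid=n_invalid,
        notes={"covariate": covariate, "sex": sex, "salmon": salmon},
    )


@dataclass
class SocialSurvivalResults:
    """Estimates, diagnostics and permutation inference from one fit."""

    model: "SocialSurvivalModel"
    cox_fits: dict = field(default_factory=dict)  # (covariate, sex, salmon) -> CoxFit
    perm_tests: dict = field(default_factory=dict)  # same keys -> PermutationResult
    matrices: dict = field(default_factory=dict)
    partitions: dict = field(default_factory=dict)
    centrality: pd.DataFrame | None = None
    person_periods: pd.DataFrame | None = None
    salmon_class: dict = field(default_factory=dict)
    differentiation: object = None
    seed: int | None = None

    @property
    def modularity_by_period(self) -> dict:
        return {p: part.modularity for p, part in self.partitions.items()}

    def summary(self) -> pd.DataFrame:
        rows = []
        for (covariate, sex, salmon), fit in self.cox_fits.items():
            perm = self.perm_tests.get((covariate, sex, salmon))
            rows.append(
                {
                    "covariate": covariate,
                    "sex": sex or "all",
                    "salmon": salmon or "all",
                    "coef": fit.coef,
                    "hazard_ratio": fit.hazard_ratio,
                    "se": fit.se,
                    "z": fit.z,
                    "n_events": fit.n_events,
                    "n_rows": fit.n_rows,
                    "p_perm": perm.p_value if perm is not None else np.nan,
                    "direction": perm.direction if perm is not None else "",
                }
            )
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "modularity": {p: _json_safe(q) for p, q in self.modularity_by_period.items()},
            "salmon_class": dict(self.salmon_class),
            "models": {},
        }
        if self.differentiation is not None:
            out["social_differentiation"] = {
                "S": self.differentiation.S,
                "r": self.differentiation.r,
            }
        for key, fit in self.cox_fits.items():
            name = "|".join(str(k) if k else "all" for k in key)
            entry = fit.as_dict()
            perm = self.perm_tests.get(key)
            if perm is not None:
                entry.update(perm.as_dict())
            out["models"][name] = entry
        return out

    def save(self, outdir) -> dict:
        """Write per-period networks, tables and a JSON results document."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p, matrix in self.matrices.items():
            cent = self.centrality[self.centrality["period"] == p]
            oio.write_network(
                matrix,
                self.partitions.get(p),
                graphml_path=outdir / f"network_{p}.graphml",
                csv_path=outdir / f"network_{p}.csv",
                centrality=cent,
                registry=self.model.registry,
            )
        self.centrality.to_csv(outdir / "centrality.csv", index=False)
        self.person_periods.to_csv(outdir / "person_periods.csv", index=False)
        oio.dump_json(self.as_dict(), outdir / "results.json")
        return {"outdir": str(outdir)}


def _json_safe(x):
    return None if (isinstance(x, float) and not np.isfinite(x)) else x


class SocialSurvivalModel:
    """Social-network survival analysis of a grouped-sighting census.

    Parameters
    ----------
    encounters, registry, salmon
        The three validated input tables (see :mod:`orcasurv.io`).
    min_community_size : int
        Communities smaller than this carry no centrality rows (default 5).
    rank_scope : {"community", "network"}
        Scope of the closeness rank transform.
    time_axis : {"study", "entry"}
        Survival clock (see :func:`orcasurv.survival.build_person_periods`).
    """

    def __init__(
        self,
        encounters: pd.DataFrame,
        registry: pd.DataFrame,
        salmon: pd.DataFrame | None = None,
        min_community_size: int = 5,
        rank_scope: str = "community",
        time_axis: str = "study",
        walktrap_steps: int = 4,
    ):
        self.registry = oio.validate_registry(registry)
        self.encounters = oio.validate_encounters(encounters, self.registry)
        self.salmon = oio.validate_salmon(salmon) if salmon is not None else None
        self.min_community_size = min_community_size
        self.rank_scope = rank_scope
        self.time_axis = time_axis
        self.walktrap_steps = walktrap_steps
        self.truth = None  # ground truth when built from a synthetic config

        self.period_bounds = bounds_from_period_ids(self.encounters["period"])
        self.periods = sorted(self.period_bounds, key=lambda p: self.period_bounds[p][0])

    @classmethod
    def from_csv(cls, encounters_path, individuals_path, salmon_path=None, **kwargs):
        if salmon_path is not None:
            enc, reg, sal = oio.read_dataset(encounters_path, individuals_path, salmon_path)
        else:
            reg = oio.validate_registry(pd.read_csv(individuals_path, dtype=str))
            enc = oio.validate_encounters(pd.read_csv(encounters_path, dtype=str), reg)
            sal = None
        return cls(enc, reg, sal, **kwargs)

    @classmethod
    def from_synthetic(cls, config, **kwargs):
        from .synthetic import simulate_dataset

        enc, reg, sal, truth = simulate_dataset(config)
        model = cls(enc, reg, sal, **kwargs)
        model.truth = truth
        return model

    # ------------------------------------------------------------------
    def _year_to_period(self) -> dict[int, str]:
        return {
            y: p for p, (lo, hi) in self.period_bounds.items() for y in range(lo, hi)
        }

    def build_networks(self):
        matrices, partitions = {}, {}
        for p in self.periods:
            m = compute_sri(self.encounters, p)
            matrices[p] = m
            if m.n_nodes:
                partitions[p] = detect_communities(
                    m, steps=self.walktrap_steps, min_community_size=self.min_community_size
                )
        return matrices, partitions

    def build_centrality(self, matrices, partitions) -> pd.DataFrame:
        tables = [
            centrality_table(
                matrices[p], partitions[p], self.min_community_size, self.rank_scope
            )
            for p in partitions
        ]
        tables = [t for t in tables if not t.empty]
        if not tables:
            return pd.DataFrame(columns=CENTRALITY_COLUMNS)
        return pd.concat(tables, ignore_index=True)

    def fit(
        self,
        covariates: tuple[str, ...] = ("degree_norm", "closeness_rank_norm"),
        sexes: tuple = ("M", "F"),
        salmon_strata: tuple | None = None,
        n_perm: int = 10000,
        n_imp: int = 1000,
        seed: int | None = None,
        differentiation: bool = True,
    ) -> SocialSurvivalResults:
        """Run the full pipeline and fit every sex × salmon-stratum Cox model.

        ``salmon_strata`` defaults to ``(None, "low", "high")`` when a salmon
        series is available and ``(None,)`` otherwise; requesting a salmon
        stratum explicitly without a salmon series is an error
        (classify_salmon has nothing to classify).  Models whose subset has no
        events are skipped rather than fatal.  ``n_perm=0`` skips permutation
        inference and reports estimates only.
        """
        explicit_strata = salmon_strata is not None
        if explicit_strata and any(s is not None for s in salmon_strata) and self.salmon is None:
            raise ValueError(
                "survival stage: salmon-stratified models requested but no salmon "
                "series was provided (classify_salmon)"
            )
        rng = np.random.default_rng(seed)
        matrices, partitions = self.build_networks()
        cent = self.build_centrality(matrices, partitions)
        salmon_class = {}
        if self.salmon is not None:
            try:
                salmon_class = classify_salmon_periods(self.salmon, self._year_to_period())
            except ValueError as exc:  # e.g. fewer than 4 periods: no quartile
                if explicit_strata and any(s is not None for s in salmon_strata):
                    raise ValueError(f"survival stage (classify_salmon): {exc}") from exc
                warnings.warn(f"salmon classification skipped: {exc}")
        if not explicit_strata:
            salmon_strata = (None, "low", "high") if salmon_class else (None,)
        starts = {p: float(lo) for p, (lo, hi) in self.period_bounds.items()}
        stops = {p: float(hi) for p, (lo, hi) in self.period_bounds.items()}
        person_periods = build_person_periods(
            self.registry, cent, starts, stops, salmon_class, time_axis=self.time_axis
        )
        results = SocialSurvivalResults(
            model=self,
            matrices=matrices,
            partitions=partitions,
            centrality=cent,
            person_periods=person_periods,
            salmon_class=salmon_class,
            seed=seed,
        )
        strata = [s for s in salmon_strata if s is None or salmon_class]
        for covariate in covariates:
            for sex in sexes:
                for salmon in strata:
                    try:
                        fit = fit_cox(person_periods, covariate, sex=sex, salmon=salmon)
                    except ValueError:
                        continue
                    results.cox_fits[(covariate, sex, salmon)] = fit
                    if n_perm > 0:
                        try:
                            results.perm_tests[(covariate, sex, salmon)] = permutation_cox_test(
                                person_periods,
                                self.registry,
                                covariate,
                                sex=sex,
                                salmon=salmon,
                                n_perm=n_perm,
                                n_imp=n_imp,
                                seed=rng,
                            )
                        except ValueError:
                            # degenerate subset (e.g. no covariate variation in
                            # any risk set): estimate kept, no permutation p
                            pass
        if differentiation and partitions:
            # pool within-community dyads over periods; labels are per period
            ks, ns = [], []
            for p, part in partitions.items():
                k, n = aggregate_dyad_counts([matrices[p]], within_partition=part.assignment)
                ks.append(k)
                ns.append(n)
            k = np.concatenate(ks) if ks else np.zeros(0)
            n = np.concatenate(ns) if ns else np.zeros(0)
            if (n > 0).sum() >= 2:
                results.differentiation = estimate_social_differentiation(k, n)
        return results
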