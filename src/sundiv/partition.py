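"""Metacommunity/subcommunity partitioning designs and their summaries.

Four designs cover the spatial and temporal questions a repeated plot-census
network can answer:

* ``spatial_zone`` — one census year; MC = one ecological zone, SC = plot.
* ``spatial_ecosystem`` — one census year; MC = whole network, SC = plot,
  with the same number of plots drawn from each zone.
* ``temporal_psp`` — MC = one plot pooled over all censuses, SC = the plot
  at each census (temporal representativeness / turnover).
* ``temporal_zone`` — as above with the zone's pooled composition per census.

Zones with more plots than the balanced target are repeatedly subsampled
without replacement (default 30 plots, 100 iterations) so that no zone
dominates the ecosystem-level metacommunity.  Summaries average subcommunity
values on the power-mean scale of order ``1 - q`` and attach bootstrap
percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .census import CensusTable
from .diversity import (
    Metacommunity,
    build_metacommunity,
    metacommunity_average,
    metacommunity_gamma,
    subcommunity_alpha_bar,
    subcommunity_gamma,
    subcommunity_rho_bar,
)

DESIGN_KINDS = ("spatial_zone", "spatial_ecosystem", "temporal_psp", "temporal_zone")

RESULT_COLUMNS = [
    "design", "iteration", "measure", "q", "group", "year",
    "subcommunity", "weight", "value",
]


class CapacityError(ValueError):
    """A zone holds fewer plots than the requested subsample size."""


class IncompleteSeriesError(ValueError):
    """A unit is missing one of the required census years."""


@dataclass
class DesignSpec:
    """Configuration of one partitioning design.

    ``n_per_zone=None`` disables balancing and uses every available plot
    (then a single iteration suffices and is all that is generated when no
    randomness remains).
    """

    kind: str
    census_year: int | None = None
    zone: str = "all"
    n_per_zone: int | None = 30
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.kind.startswith("spatial") and self.census_year is None:
            raise ValueError(f"{self.kind} requires census_year")


@dataclass
class DesignRealization:
    """One realized metacommunity with per-subcommunity annotations."""

    mc: Metacommunity
    labels: list[str]
    groups: list[str]           # zone (or unit) of each subcommunity
    years: list[int]            # census year of each subcommunity
    iteration: int
    design_label: str


def _subsample(plots: Sequence[str], n: int | None, rng: np.random.Generator,
               zone: str) -> list[str]:
    plots = list(plots)
    if n is None or len(plots) == n:
        return plots
    if len(plots) < n:
        raise CapacityError(f"zone {zone!r} has {len(plots)} plots, needs {n}")
    idx = rng.choice(len(plots), size=n, replace=False)
    return [plots[i] for i in sorted(idx)]


def _needs_sampling(table: CensusTable, spec: DesignSpec, zones: list[str]) -> bool:
    if spec.n_per_zone is None:
        return False
    by_zone = table.metadata.groupby("zone")["plot_id"].count()
    return any(by_zone.get(z, 0) > spec.n_per_zone for z in zones)


def build_design(table: CensusTable, spec: DesignSpec) -> list[DesignRealization]:
    """Materialize every realization (subsampling iteration) of a design.

    Draws are without replacement within a zone, independent across
    iterations, and reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    meta = table.metadata
    zone_plots = {
        z: sorted(meta.loc[meta["zone"] == z, "plot_id"]) for z in meta["zone"].unique()
    }
    zmap = table.zone_of()
    species_all = np.array(sorted(table.records["species"].unique()))
    out: list[DesignRealization] = []

    def realize(cols: np.ndarray, labels, groups_, years_, it, design_label):
        keep = cols.sum(axis=1) > 0
        mc = build_metacommunity(cols[keep], species_all[keep].tolist(), list(labels))
        out.append(DesignRealization(mc, list(labels), list(groups_), list(years_),
                                     it, design_label))

    if spec.kind in ("spatial_zone", "spatial_ecosystem"):
        year = int(spec.census_year)
        if year not in table.years:
            raise ValueError(f"census year {year} not present in table")
        rec = table.records
        sub = rec.loc[rec["year"] == year]
        wide = sub.pivot_table(index="species", columns="plot_id", values="count",
                               aggfunc="sum", fill_value=0)
        wide = wide.reindex(index=species_all, fill_value=0)
        col_of = {p: i for i, p in enumerate(wide.columns)}
        counts_all = np.asarray(wide, dtype=np.int64)

        def cols_for(plots):
            return counts_all[:, [col_of[p] for p in plots if p in col_of]], \
                   [p for p in plots if p in col_of]

        zones = sorted(zone_plots) if spec.zone == "all" else [spec.zone]
        n_iter = spec.iterations if _needs_sampling(table, spec, zones) else 1
        for it in range(n_iter):
            if spec.kind == "spatial_zone":
                for zone in zones:
                    plots = _subsample(zone_plots[zone], spec.n_per_zone, rng, zone)
                    cols, labels = cols_for(plots)
                    realize(cols, labels, [zone] * len(labels), [year] * len(labels),
                            it, f"spatial_zone:{zone}:{year}")
            else:
                plots: list[str] = []
                for zone in zones:
                    plots += _subsample(zone_plots[zone], spec.n_per_zone, rng, zone)
                cols, labels = cols_for(plots)
                realize(cols, labels, [zmap[p] for p in labels], [year] * len(labels),
                        it, f"spatial_ecosystem:{year}")
        return out

    years = table.years
    rec = table.records
    key = "plot_id" if spec.kind == "temporal_psp" else "zone"
    wide = rec.pivot_table(index="species", columns=[key, "year"], values="count",
                           aggfunc="sum", fill_value=0)
    wide = wide.reindex(index=species_all, fill_value=0)
    counts_all = np.asarray(wide, dtype=np.int64)
    col_of = {c: i for i, c in enumerate(wide.columns)}
    if spec.kind == "temporal_psp":
        units = [(p, zmap[p]) for p in sorted(zmap)]
    else:
        zones = sorted(zone_plots) if spec.zone == "all" else [spec.zone]
        units = [(z, z) for z in zones]
    for unit, zone in units:
        missing = [y for y in years
                   if (unit, y) not in col_of or counts_all[:, col_of[(unit, y)]].sum() == 0]
        if missing:
            raise IncompleteSeriesError(
                f"unit {unit!r} is missing census year(s) {missing}"
            )
        cols = counts_all[:, [col_of[(unit, y)] for y in years]]
        labels = [f"{unit}|{y}" for y in years]
        realize(cols, labels, [zone] * len(labels), list(years), 0,
                f"{spec.kind}:{unit}")
    return out


def run_design(
    realizations: Iterable[DesignRealization], q_list: Sequence[float]
) -> pd.DataFrame:
    """Compute all four measures for every realization, as a tidy table.

    ``gamma_meta`` rows carry the sentinel subcommunity ``__meta__``.
    """
    realizations = list(realizations)
    if not realizations:
        raise ValueError("no design realizations supplied")
    rows = []
    for real in realizations:
        for q in q_list:
            for fn, name in (
                (subcommunity_alpha_bar, "alpha_bar"),
                (subcommunity_rho_bar, "rho_bar"),
                (subcommunity_gamma, "gamma_sub"),
            ):
                res = fn(real.mc, q)
                for lab, grp, yr, wgt, val in zip(
                    real.labels, real.groups, real.years, real.mc.w, res.values
                ):
                    rows.append((real.design_label, real.iteration, name, q,
                                 grp, yr, lab, wgt, val))
            rows.append((real.design_label, real.iteration, "gamma_meta", q,
                         "all", -1, "__meta__", 1.0, metacommunity_gamma(real.mc, q)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _row_power_means(X: np.ndarray, W: np.ndarray, q: float, convention: str) -> np.ndarray:
    """Row-wise order-(1-q) weighted power means (vectorized bootstrap core)."""
    if convention == "paper_literal":
        order = {0.0: 1.0, 1.0: -1.0, 2.0: 0.0}.get(float(q), 1.0 - q)
    else:
        order = 1.0 - q
    W = W / W.sum(axis=1, keepdims=True)
    if abs(order) < 1e-9:
        return np.exp(np.sum(W * np.log(X), axis=1))
    return np.sum(W * X**order, axis=1) ** (1.0 / order)


@dataclass
class SummaryRow:
    measure: str
    q: float
    group: str
    year: int
    mean: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def summarize(
    results: pd.DataFrame,
    q: float,
    group_by: Sequence[str] = ("group", "year"),
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    convention: str = "power",
) -> pd.DataFrame:
    """Summarize per-subcommunity values with bootstrap confidence intervals.

    The point estimate is the order-(1-q) power-mean average over
    subcommunities within each iteration, then the arithmetic mean over
    iterations.  The CI is a seeded percentile bootstrap (default B=1000)
    over the pooled iteration x subcommunity values; a single-subcommunity
    group degenerates to a zero-width interval and is flagged.
    """
    sub = results.loc[(results["measure"] != "gamma_meta") & (results["q"] == q)]
    if sub.empty:
        raise ValueError(f"no subcommunity results at q={q}")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    rows: list[SummaryRow] = []
    for keys, grp in sub.groupby(["measure", *group_by], sort=True):
        measure = keys[0]
        per_iter = [
            metacommunity_average(g["value"], g["weight"], q, convention)
            for _, g in grp.groupby("iteration")
        ]
        point = float(np.mean(per_iter))
        vals = grp["value"].to_numpy()
        wgts = grp["weight"].to_numpy()
        if len(vals) == 1:
            lo = hi = point
            degenerate = True
        else:
            n = len(vals)
            idx = rng.integers(0, n, size=(n_boot, n))
            boots = _row_power_means(vals[idx], wgts[idx], q, convention)
            lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
            degenerate = False
        gdict = dict(zip(group_by, keys[1:]))
        rows.append(SummaryRow(
            measure, q, str(gdict.get("group", "all")), int(gdict.get("year", -1)),
            point, float(min(lo, point)), float(max(hi, point)), degenerate,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def zone_representativeness_series(
    table: CensusTable, q: float = 1.0, convention: str = "power"
) -> pd.DataFrame:
    """Zone-mean spatial rho-bar per census year (homogenization tracker).

    For each census, MC = zone, SC = every plot of the zone (no balancing);
    plot values are averaged on the order-(1-q) power-mean scale.  A rising
    series means plots are converging in composition — biotic
    homogenization.  Columns: ``zone, year, q, rho_bar_mean``.
    """
    rows = []
    for year in table.years:
        reals = build_design(
            table,
            DesignSpec("spatial_zone", census_year=year, n_per_zone=None, iterations=1),
        )
        res = run_design(reals, [q])
        sub = res.loc[res["measure"] == "rho_bar"]
        for zone, g in sub.groupby("group"):
            rows.append(
                (zone, year, q,
                 metacommunity_average(g["value"], g["weight"], q, convention))
            )
    return pd.DataFrame(rows, columns=["zone", "year", "q", "rho_bar_mean"])


def temporal_representativeness(
    table: CensusTable, level: str, q_list: Sequence[float]
) -> pd.DataFrame:
    """Temporal rho-bar per unit (plot or zone) per census year.

    The metacommunity is the unit pooled over every census in the table; the
    subcommunities are its composition at each census.  Low values mark high
    compositional turnover.  Columns: ``unit, zone, year, q, rho_bar``.
    """
    if level not in ("psp", "zone"):
        raise ValueError("level must be 'psp' or 'zone'")
    kind = "temporal_psp" if level == "psp" else "temporal_zone"
    reals = build_design(table, DesignSpec(kind=kind))
    rows = []
    for real in reals:
        unit = real.design_label.split(":", 1)[1]
        for q in q_list:
            res = subcommunity_rho_bar(real.mc, q)
            for lab, zone, yr, val in zip(real.labels, real.groups, real.years, res.values):
                rows.append((unit, zone, yr, q, val))
    return pd.DataFrame(rows, columns=["unit", "zone", "year", "q", "rho_bar"])
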