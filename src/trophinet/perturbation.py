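"""Species-removal experiments and trait-degree regressions.

Covers the jackknife contribution of each consumer to nestedness
(delta-N_i = N - N_i, where N_i is the NODF after removing consumer i and
dropping any resource columns the removal emptied), targeted group-removal
tests against random same-size removals, the main-vs-secondary resource
sensitivity comparison, and ordinary least-squares regressions of network
roles on log10 body mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .network_core import BipartiteNetwork, InteractionRecord, TraitTable, build_network
from .structure_metrics import nodf

__all__ = [
    "RemovalResult",
    "GroupRemovalResult",
    "RegressionResult",
    "SecondaryComparison",
    "jackknife_nestedness",
    "group_removal_test",
    "secondary_resource_comparison",
    "trait_degree_regression",
    "delta_regressions",
]


def _reduced_nodf(A: np.ndarray, keep_rows: np.ndarray) -> float:
    """NODF of the row-subset matrix with emptied columns dropped."""
    sub = A[keep_rows]
    sub = sub[:, sub.sum(axis=0) > 0]
    return nodf(sub)


@dataclass
class RemovalResult:
    """Per-consumer jackknife contributions to nestedness."""

    species: list[str]
    nodf_full: float
    nodf_without: np.ndarray  #: N_i per consumer
    delta_n: np.ndarray  #: N - N_i
    degree: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "degree": self.degree,
                "nodf_without": self.nodf_without,
                "delta_n": self.delta_n,
            }
        ).set_index("species")


@dataclass(frozen=True)
class GroupRemovalResult:
    """Targeted removal vs random same-size removals."""

    removed: tuple[str, ...]
    nodf_full: float
    observed_n: float  #: NODF after removing the target set
    null_values: np.ndarray = field(repr=False)
    p_value: float  #: lower-tail: is the observed NODF smaller than random?

    @property
    def pct_change(self) -> float:
        """Percent change in NODF caused by the removal (negative = loss)."""
        return 100.0 * (self.observed_n - self.nodf_full) / self.nodf_full


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit summary."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  #: two-sided t-test on the slope
    n: int


@dataclass(frozen=True)
class SecondaryComparison:
    """Main-only vs main+secondary network nestedness."""

    nodf_full: float
    nodf_main_only: float
    n_resources_lost: int
    p_value: float  #: two-sided vs random removal of as many resources
    degenerate: bool  #: True when filtering removed no resources


def jackknife_nestedness(net: BipartiteNetwork) -> RemovalResult:
    """Remove each consumer in turn and recompute NODF on the reduced
    network (emptied resource columns dropped)."""
    n = net.n_consumers
    if n < 3:
        raise ValueError("jackknife needs at least three consumers")
    N = nodf(net)
    without = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        without[i] = _reduced_nodf(net.A, keep)
    return RemovalResult(
        species=list(net.consumers),
        nodf_full=N,
        nodf_without=without,
        delta_n=N - without,
        degree=net.consumer_degrees,
    )


def group_removal_test(
    net: BipartiteNetwork,
    species_set: list[str] | set[str],
    n_reps: int = 1000,
    seed: int | None = None,
    exclude_targets: bool = False,
) -> GroupRemovalResult:
    """NODF after removing a target consumer set, compared with removals of
    the same number of consumers drawn uniformly at random.

    The p-value is lower-tailed with the add-one correction: small p means
    the target removal degrades nestedness more than random removals do.
    With ``exclude_targets=True`` random subsets avoid the target species.
    """
    targets = sorted({s.strip() for s in species_set})
    unknown = set(targets) - set(net.consumers)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    n = net.n_consumers
    s = len(targets)
    if s >= n:
        raise ValueError("cannot remove every consumer")
    N = nodf(net)
    if s == 0:
        return GroupRemovalResult(
            removed=(), nodf_full=N, observed_n=N, null_values=np.empty(0), p_value=1.0
        )
    target_idx = np.array([net.consumers.index(t) for t in targets])
    keep = np.ones(n, dtype=bool)
    keep[target_idx] = False
    observed = _reduced_nodf(net.A, keep)
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(n), target_idx) if exclude_targets else np.arange(n)
    null_vals = np.empty(n_reps)
    for r in range(n_reps):
        drop = rng.choice(pool, size=s, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[drop] = False
        null_vals[r] = _reduced_nodf(net.A, mask)
    p = (1 + int(np.sum(null_vals <= observed))) / (1 + n_reps)
    return GroupRemovalResult(
        removed=tuple(targets),
        nodf_full=N,
        observed_n=observed,
        null_values=null_vals,
        p_value=p,
    )


def secondary_resource_comparison(
    records: list[InteractionRecord],
    n_reps: int = 5000,
    seed: int | None = None,
) -> SecondaryComparison:
    """Does dropping secondary-rank interactions change nestedness more than
    dropping the same number of resource categories at random?

    Builds the full (main + secondary) and the main-only networks, counts
    the resource columns lost to the filtering, and compares the NODF shift
    against ``n_reps`` random removals of that many resource columns from
    the full network (rows emptied by a removal are dropped before NODF).
    The p-value is two-sided on the shift magnitude.
    """
    full = build_network(records, include_secondary=True)
    main_only = build_network(records, include_secondary=False)
    n_lost = full.n_resources - main_only.n_resources
    nodf_full = nodf(full)
    nodf_main = nodf(main_only)
    if n_lost == 0:
        return SecondaryComparison(
            nodf_full=nodf_full,
            nodf_main_only=nodf_main,
            n_resources_lost=0,
            p_value=1.0,
            degenerate=True,
        )
    rng = np.random.default_rng(seed)
    m = full.n_resources
    shift = abs(nodf_main - nodf_full)
    null_shifts = np.empty(n_reps)
    for r in range(n_reps):
        drop = rng.choice(m, size=n_lost, replace=False)
        cols = np.ones(m, dtype=bool)
        cols[drop] = False
        sub = full.A[:, cols]
        sub = sub[sub.sum(axis=1) > 0]
        null_shifts[r] = abs(nodf(sub) - nodf_full)
    p = (1 + int(np.sum(null_shifts >= shift))) / (1 + n_reps)
    return SecondaryComparison(
        nodf_full=nodf_full,
        nodf_main_only=nodf_main,
        n_resources_lost=n_lost,
        p_value=p,
        degenerate=False,
    )


def _ols(y: np.ndarray, x: np.ndarray) -> RegressionResult:
    if len(y) < 3:
        raise ValueError("regression needs at least three points")
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    r2 = float(fit.rsquared)
    p = float(fit.pvalues[1])
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r2 if np.isfinite(r2) else 0.0,  # degenerate constant response
        p_value=p if np.isfinite(p) else 1.0,
        n=len(y),
    )


def trait_degree_regression(
    net: BipartiteNetwork,
    traits: TraitTable,
    subset_family: str | None = None,
) -> RegressionResult:
    """OLS of consumer degree on log10 body mass (grams), optionally
    restricted to one family."""
    traits.check_covers(net)
    species = net.consumers
    deg = net.consumer_degrees.astype(float)
    if subset_family is not None:
        sel = [i for i, s in enumerate(species) if traits.family_of(s) == subset_family]
        if not sel:
            raise ValueError(f"no consumers in family {subset_family!r}")
        species = [species[i] for i in sel]
        deg = deg[sel]
    mass = np.array([traits.mass_of(s) for s in species])
    if (mass <= 0).any():
        raise ValueError("body masses must be positive")
    return _ols(deg, np.log10(mass))


def delta_regressions(
    removal: RemovalResult, traits: TraitTable
) -> tuple[RegressionResult, RegressionResult]:
    """Regress jackknife delta-N on log10 body mass and on degree."""
    mass = np.array([traits.mass_of(s) for s in removal.species])
    on_mass = _ols(removal.delta_n, np.log10(mass))
    on_degree = _ols(removal.delta_n, removal.degree.astype(float))
    return on_mass, on_degree
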