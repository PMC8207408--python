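"""Lifestyle-by-module association: contingency tabulation, a
margin-preserving randomization test, and Bray-Curtis dissimilarity
between module lifestyle compositions.

The randomization keeps the number of consumers per lifestyle and per
module fixed in every replicate (a random reassignment of lifestyle labels
across consumers), so each cell's null distribution is multivariate
hypergeometric; upper and lower tail probabilities are both reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .module_detection import ModulePartition
from .network_core import BipartiteNetwork, TraitTable

__all__ = [
    "GuildModuleCounts",
    "CellPValues",
    "tabulate_guilds",
    "guild_randomization_test",
    "bray_curtis_modules",
]


@dataclass(frozen=True)
class GuildModuleCounts:
    """Module x lifestyle contingency table of consumer counts."""

    counts: np.ndarray  #: shape (n_modules, n_lifestyles), nonnegative ints
    lifestyles: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or (c < 0).any():
            raise ValueError("counts must be a nonnegative 2-D table")
        if c.shape[1] != len(self.lifestyles):
            raise ValueError("lifestyle labels must match table columns")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "lifestyles", tuple(self.lifestyles))

    @property
    def module_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def lifestyle_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_consumers(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"module_{i}" for i in range(len(self.counts))],
            columns=list(self.lifestyles),
        )


@dataclass(frozen=True)
class CellPValues:
    """Per-cell randomization tail probabilities and significance flags."""

    p_upper: np.ndarray = field(repr=False)
    p_lower: np.ndarray = field(repr=False)
    flags: np.ndarray = field(repr=False)  #: "significant" | "marginal" | "ns"
    n_reps: int = 0

    def flag_frame(self, lifestyles: tuple[str, ...]) -> pd.DataFrame:
        return pd.DataFrame(
            self.flags,
            index=[f"module_{i}" for i in range(len(self.flags))],
            columns=list(lifestyles),
        )


def tabulate_guilds(
    net: BipartiteNetwork,
    partition: ModulePartition,
    traits: TraitTable,
    lifestyles: tuple[str, ...] | None = None,
) -> GuildModuleCounts:
    """Count consumers per (module, lifestyle) cell."""
    traits.check_covers(net)
    if lifestyles is None:
        from .network_core import LIFESTYLES

        lifestyles = LIFESTYLES
    lidx = {l: j for j, l in enumerate(lifestyles)}
    counts = np.zeros((partition.n_modules, len(lifestyles)), dtype=np.int64)
    for i, sp in enumerate(net.consumers):
        ls = traits.lifestyle_of(sp)
        if ls not in lidx:
            raise ValueError(f"lifestyle {ls!r} not in {lifestyles}")
        counts[int(partition.g[i]), lidx[ls]] += 1
    return GuildModuleCounts(counts=counts, lifestyles=tuple(lifestyles))


def guild_randomization_test(
    counts: GuildModuleCounts | np.ndarray,
    n_reps: int = 1000,
    seed: int | None = None,
    significant_at: float = 0.025,
    marginal_at: float = 0.05,
) -> CellPValues:
    """Randomization test of each cell against margin-preserving label
    shuffles.

    Each replicate reassigns lifestyles to consumers uniformly at random
    while preserving both the module sizes and the lifestyle totals; tail
    probabilities use the add-one correction.  A cell is flagged
    ``significant`` when min(p_upper, p_lower) <= ``significant_at``
    (two-sided 0.05 by default) and ``marginal`` when <= ``marginal_at``.
    """
    C = np.asarray(counts.counts if isinstance(counts, GuildModuleCounts) else counts)
    if C.sum() == 0:
        raise ValueError("empty contingency table")
    n_mod, n_ls = C.shape
    module_sizes = C.sum(axis=1)
    # expanded vectors: one entry per consumer
    module_of = np.repeat(np.arange(n_mod), module_sizes)
    lifestyle_labels = np.repeat(np.arange(n_ls), C.sum(axis=0))
    rng = np.random.default_rng(seed)
    ge = np.zeros_like(C, dtype=np.int64)
    le = np.zeros_like(C, dtype=np.int64)
    for _ in range(n_reps):
        perm = rng.permutation(lifestyle_labels)
        rand = np.zeros_like(C)
        np.add.at(rand, (module_of, perm), 1)
        ge += rand >= C
        le += rand <= C
    p_upper = (1 + ge) / (1 + n_reps)
    p_lower = (1 + le) / (1 + n_reps)
    p_min = np.minimum(p_upper, p_lower)
    flags = np.full(C.shape, "ns", dtype=object)
    flags[p_min <= marginal_at] = "marginal"
    flags[p_min <= significant_at] = "significant"
    return CellPValues(p_upper=p_upper, p_lower=p_lower, flags=flags, n_reps=n_reps)


def bray_curtis_modules(counts: GuildModuleCounts | np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between module lifestyle-count
    vectors (raw counts, not proportions).

    BC(a, b) = sum_l |c_al - c_bl| / sum_l (c_al + c_bl); two empty modules
    get BC = 0 by convention.  Symmetric with zero diagonal, in [0, 1].
    """
    C = np.asarray(
        counts.counts if isinstance(counts, GuildModuleCounts) else counts, dtype=float
    )
    if C.shape[0] < 2:
        raise ValueError("need at least two modules")
    diff = np.abs(C[:, None, :] - C[None, :, :]).sum(axis=2)
    tot = (C[:, None, :] + C[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(tot > 0, diff / np.where(tot > 0, tot, 1), 0.0)
    np.fill_diagonal(bc, 0.0)
    return bc
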