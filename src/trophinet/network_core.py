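"""Domain types and I/O for binary consumer-resource networks.

A trophic network is stored as a binary incidence matrix ``A`` (consumers as
rows, resources as columns, ``A[i, j] = 1`` when consumer *i* feeds on
resource *j*).  Interaction records, consumer trait tables and resource
category mappings are exchanged as plain UTF-8 comma-delimited CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIFESTYLES",
    "RANKS",
    "InteractionRecord",
    "BipartiteNetwork",
    "TraitTable",
    "build_network",
    "read_edge_list",
    "write_edge_list",
    "read_traits",
    "write_traits",
    "read_matrix",
    "write_matrix",
    "read_mapping",
    "apply_mapping",
]

#: The closed habitat-use (lifestyle) vocabulary for consumers.
LIFESTYLES = (
    "aquatic",
    "arboreal",
    "fossorial",
    "semi-arboreal",
    "semi-fossorial",
    "terrestrial",
)

#: Interaction importance ranks: a "main" resource is a staple of the
#: consumer's diet, a "secondary" one is only occasionally taken.
RANKS = ("main", "secondary")


@dataclass(frozen=True)
class InteractionRecord:
    """One observed consumer-resource interaction.

    ``rank`` defaults to ``"main"``; ids are whitespace-trimmed and
    case-sensitive.
    """

    consumer_id: str
    resource_id: str
    rank: str = "main"

    def __post_init__(self) -> None:
        object.__setattr__(self, "consumer_id", self.consumer_id.strip())
        object.__setattr__(self, "resource_id", self.resource_id.strip())
        if not self.consumer_id or not self.resource_id:
            raise ValueError("consumer_id and resource_id must be nonempty")
        if self.rank not in RANKS:
            raise ValueError(f"unknown interaction rank {self.rank!r}; expected one of {RANKS}")


class BipartiteNetwork:
    """Binary bipartite incidence matrix with named consumers and resources.

    Invariants enforced at construction: entries are 0/1, ids are unique and
    nonempty, and no consumer row is all-zero (a consumer without any
    recorded diet is not part of the network).  Resource columns may not be
    all-zero either; emptied columns are dropped by the operations that can
    create them (filtering, species removal) before metrics are computed.
    """

    __slots__ = ("consumers", "resources", "A")

    def __init__(
        self,
        consumers: Sequence[str],
        resources: Sequence[str],
        A: np.ndarray,
    ) -> None:
        consumers = [str(c).strip() for c in consumers]
        resources = [str(r).strip() for r in resources]
        A = np.asarray(A)
        if A.ndim != 2:
            raise ValueError("incidence matrix must be 2-D")
        n, m = A.shape
        if n < 1 or m < 1:
            raise ValueError("network needs at least one consumer and one resource")
        if len(consumers) != n or len(resources) != m:
            raise ValueError("id lists must match matrix shape")
        if any(not c for c in consumers) or any(not r for r in resources):
            raise ValueError("ids must be nonempty")
        if len(set(consumers)) != n:
            raise ValueError("duplicate consumer ids")
        if len(set(resources)) != m:
            raise ValueError("duplicate resource ids")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("incidence matrix entries must be 0 or 1")
        A = A.astype(np.int8)
        empty = np.flatnonzero(A.sum(axis=1) == 0)
        if empty.size:
            bad = [consumers[i] for i in empty]
            raise ValueError(f"consumers with no interactions are not allowed: {bad}")
        self.consumers = consumers
        self.resources = resources
        self.A = A

    # -- basic quantities -------------------------------------------------

    @property
    def n_consumers(self) -> int:
        return self.A.shape[0]

    @property
    def n_resources(self) -> int:
        return self.A.shape[1]

    @property
    def n_links(self) -> int:
        """Total number of interactions F."""
        return int(self.A.sum())

    @property
    def consumer_degrees(self) -> np.ndarray:
        return self.A.sum(axis=1).astype(np.int64)

    @property
    def resource_degrees(self) -> np.ndarray:
        return self.A.sum(axis=0).astype(np.int64)

    def degree_of(self, consumer_id: str) -> int:
        return int(self.A[self.consumers.index(consumer_id)].sum())

    # -- derived networks -------------------------------------------------

    def drop_empty_resources(self) -> "BipartiteNetwork":
        """Return a copy without all-zero resource columns."""
        keep = np.flatnonzero(self.A.sum(axis=0) > 0)
        if keep.size == self.n_resources:
            return self
        return BipartiteNetwork(
            self.consumers, [self.resources[j] for j in keep], self.A[:, keep]
        )

    def remove_consumers(self, ids: Iterable[str]) -> "BipartiteNetwork":
        """Remove the given consumers, dropping resource columns emptied by
        the removal."""
        drop = {i.strip() for i in ids}
        unknown = drop - set(self.consumers)
        if unknown:
            raise KeyError(f"unknown consumer ids: {sorted(unknown)}")
        keep = [i for i, c in enumerate(self.consumers) if c not in drop]
        if not keep:
            raise ValueError("removal would leave no consumers")
        sub = BipartiteNetwork(
            [self.consumers[i] for i in keep], self.resources, self.A[keep]
        )
        return sub.drop_empty_resources()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.consumers == other.consumers
            and self.resources == other.resources
            and np.array_equal(self.A, other.A)
        )

    def __repr__(self) -> str:
        return (
            f"BipartiteNetwork({self.n_consumers} consumers x "
            f"{self.n_resources} resources, {self.n_links} links)"
        )


@dataclass
class TraitTable:
    """Per-consumer traits: body mass (grams), family, lifestyle.

    Backed by a DataFrame indexed by consumer id with columns
    ``family``, ``body_mass_g``, ``lifestyle``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"family", "body_mass_g", "lifestyle"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate consumer ids in trait table")
        if (self.data["body_mass_g"] <= 0).any() or self.data["body_mass_g"].isna().any():
            raise ValueError("body_mass_g must be positive")
        bad = set(self.data["lifestyle"]) - set(LIFESTYLES)
        if bad:
            raise ValueError(f"unknown lifestyles: {sorted(bad)}; expected {LIFESTYLES}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def mass_of(self, consumer_id: str) -> float:
        return float(self.data.loc[consumer_id, "body_mass_g"])

    def lifestyle_of(self, consumer_id: str) -> str:
        return str(self.data.loc[consumer_id, "lifestyle"])

    def family_of(self, consumer_id: str) -> str:
        return str(self.data.loc[consumer_id, "family"])

    def check_covers(self, net: BipartiteNetwork) -> None:
        """Raise unless every network consumer has exactly one trait row."""
        missing = set(net.consumers) - set(self.data.index)
        if missing:
            raise ValueError(f"consumers missing from trait table: {sorted(missing)}")


def build_network(
    records: Sequence[InteractionRecord], include_secondary: bool = True
) -> BipartiteNetwork:
    """Assemble an incidence matrix from interaction records.

    Duplicate records collapse to a single 1.  With
    ``include_secondary=False`` records of rank ``secondary`` are dropped and
    resource columns left all-zero are removed.  Consumer and resource order
    is first-appearance order over the *retained* records.
    """
    if not records:
        raise ValueError("no interaction records given")
    kept = [r for r in records if include_secondary or r.rank == "main"]
    if not kept:
        raise ValueError("all records filtered out (only secondary-rank records given)")
    consumers: list[str] = []
    resources: list[str] = []
    cidx: dict[str, int] = {}
    ridx: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for r in kept:
        if r.consumer_id not in cidx:
            cidx[r.consumer_id] = len(consumers)
            consumers.append(r.consumer_id)
        if r.resource_id not in ridx:
            ridx[r.resource_id] = len(resources)
            resources.append(r.resource_id)
        pairs.add((cidx[r.consumer_id], ridx[r.resource_id]))
    A = np.zeros((len(consumers), len(resources)), dtype=np.int8)
    for i, j in pairs:
        A[i, j] = 1
    return BipartiteNetwork(consumers, resources, A)


# -- CSV plumbing ---------------------------------------------------------


def read_edge_list(path: str | Path) -> list[InteractionRecord]:
    """Read interaction records from a CSV with columns
    ``consumer,resource[,rank]``; a missing rank column (or empty cell)
    defaults to ``main``."""
    df = pd.read_csv(path, dtype=str)
    required = {"consumer", "resource"}
    if not required <= set(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}, got {list(df.columns)}")
    if "rank" not in df.columns:
        df["rank"] = "main"
    df["rank"] = df["rank"].fillna("main")
    return [
        InteractionRecord(row.consumer, row.resource, row.rank)
        for row in df.itertuples(index=False)
    ]


def write_edge_list(records: Sequence[InteractionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "consumer": [r.consumer_id for r in records],
            "resource": [r.resource_id for r in records],
            "rank": [r.rank for r in records],
        }
    ).to_csv(path, index=False)


def read_traits(path: str | Path) -> TraitTable:
    """Read a trait CSV with columns ``species,family,body_mass_g,lifestyle``."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    df["species"] = df["species"].astype(str).str.strip()
    df = df.set_index("species")
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.data.rename_axis("species").to_csv(path)


def read_matrix(path: str | Path) -> BipartiteNetwork:
    """Read an incidence matrix CSV: first column consumer ids, header row
    resource ids, cells 0/1."""
    df = pd.read_csv(path, index_col=0)
    return BipartiteNetwork(
        [str(c) for c in df.index], [str(r) for r in df.columns], df.to_numpy()
    )


def write_matrix(net: BipartiteNetwork, path: str | Path) -> None:
    pd.DataFrame(net.A, index=net.consumers, columns=net.resources).to_csv(path)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a fine-to-coarse resource category mapping CSV (columns
    ``fine,coarse``)."""
    df = pd.read_csv(path, dtype=str)
    if not {"fine", "coarse"} <= set(df.columns):
        raise ValueError("mapping CSV must have columns fine,coarse")
    return {f.strip(): c.strip() for f, c in zip(df["fine"], df["coarse"])}


def apply_mapping(net: BipartiteNetwork, mapping: Mapping[str, str]) -> BipartiteNetwork:
    """Re-categorize resources: each coarse column is the logical OR of the
    fine columns mapped to it.  The mapping must cover every resource; coarse
    column order is first appearance of each coarse label."""
    missing = [r for r in net.resources if r not in mapping]
    if missing:
        raise KeyError(f"mapping missing resources: {missing}")
    coarse: list[str] = []
    cidx: dict[str, int] = {}
    for r in net.resources:
        lab = str(mapping[r]).strip()
        if not lab:
            raise ValueError(f"empty coarse label for resource {r!r}")
        if lab not in cidx:
            cidx[lab] = len(coarse)
            coarse.append(lab)
    A = np.zeros((net.n_consumers, len(coarse)), dtype=np.int8)
    for j, r in enumerate(net.resources):
        A[:, cidx[mapping[r].strip()]] |= net.A[:, j]
    return BipartiteNetwork(net.consumers, coarse, A)
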