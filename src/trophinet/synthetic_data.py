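"""Synthetic consumer-resource networks with known planted structure.

Three generators emulate the statistical features the analysis pipeline is
built around, so every stage can be exercised without field data:

* ``generate_nested`` — a size-structured diet hierarchy: resources are
  globally ranked, each consumer's diet breadth grows with log body mass,
  and small consumers eat subsets of what large consumers eat (a perfectly
  nested matrix at zero noise).
* ``generate_modular`` — habitat-driven compartments: planted consumer and
  resource blocks with dense within-block and sparse between-block links,
  and block-correlated lifestyles.
* ``generate_combined`` — the modular background plus a few very large,
  high-degree "connector" consumers linked into every block, emulating the
  role large generalist snakes (boids) play in real trophic networks.

All generators are bit-reproducible given the config seed; defaults target
the sparse (~10% fill) regime with right-skewed consumer degrees typical
of the community data this package analyzes (62 consumers, 26 resource
categories, 6 modules, 5 connectors).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network_core import LIFESTYLES, BipartiteNetwork, TraitTable

__all__ = ["GeneratorConfig", "generate_nested", "generate_modular", "generate_combined"]

CONNECTOR_FAMILY = "ConnectorFam"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generators.

    Masses are lognormal: log10(mass_g) ~ Normal(mass_log_mean, mass_log_sd);
    the defaults span roughly 4 orders of magnitude in grams.  In the nested
    generator the expected diet breadth is
    ``breadth_intercept + breadth_slope * log10(mass)`` (clamped to [1, m]);
    ``noise_swap_rate`` is the per-link probability of relocating a link to a
    random vacant cell (fill-preserving noise).  In the modular generators
    links are Bernoulli(p_in) within blocks and Bernoulli(p_out) between,
    and each consumer carries its block's signature lifestyle with
    probability ``lifestyle_fidelity``.
    """

    n_consumers: int = 62
    n_resources: int = 26
    mass_log_mean: float = 1.8
    mass_log_sd: float = 0.7
    breadth_intercept: float = 0.1
    breadth_slope: float = 1.41
    noise_swap_rate: float = 0.10
    n_modules: int = 6
    p_in: float = 0.45
    p_out: float = 0.03
    lifestyle_fidelity: float = 0.8
    n_connectors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_consumers < 2 or self.n_resources < 2:
            raise ValueError("need at least 2 consumers and 2 resources")
        for name in ("noise_swap_rate", "p_in", "p_out", "lifestyle_fidelity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_modules < 1 or self.n_connectors < 0:
            raise ValueError("n_modules >= 1 and n_connectors >= 0 required")
        if self.mass_log_sd <= 0:
            raise ValueError("mass_log_sd must be positive")


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def _traits_frame(
    species: list[str], mass: np.ndarray, family: list[str], lifestyle: list[str]
) -> TraitTable:
    return TraitTable(
        pd.DataFrame(
            {"family": family, "body_mass_g": mass, "lifestyle": lifestyle},
            index=pd.Index(species, name="species"),
        )
    )


def _swap_noise(A: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Relocate each link to a random vacant cell of its own row with
    probability ``rate``.

    Keeping relocations within the row preserves both the total fill and
    every consumer's diet breadth, so the noise dial degrades nestedness
    without disturbing the planted degree-mass coupling."""
    if rate <= 0:
        return
    links = list(zip(*np.nonzero(A)))
    for i, j in links:
        if A[i, j] == 0 or rng.random() >= rate:
            continue
        vacant = np.flatnonzero(A[i] == 0)
        if vacant.size == 0:
            continue
        j2 = int(rng.choice(vacant))
        A[i, j] = 0
        A[i, j2] = 1


def _finalize(
    species: list[str], resources: list[str], A: np.ndarray
) -> BipartiteNetwork:
    keep = np.flatnonzero(A.sum(axis=0) > 0)
    return BipartiteNetwork(species, [resources[j] for j in keep], A[:, keep])


def generate_nested(config: GeneratorConfig) -> tuple[BipartiteNetwork, TraitTable]:
    """Size-structured nested network: consumer i takes the top-k_i ranked
    resources, with diet breadth k_i increasing in log body mass."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_consumers, config.n_resources
    logmass = rng.normal(config.mass_log_mean, config.mass_log_sd, size=n)
    mass = 10.0**logmass
    k = np.clip(
        np.round(config.breadth_intercept + config.breadth_slope * logmass), 1, m
    ).astype(int)
    A = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        A[i, : k[i]] = 1
    _swap_noise(A, config.noise_swap_rate, rng)
    species = _names("consumer_", n)
    resources = _names("resource_", m)
    families = [f"Fam{chr(65 + int(x))}" for x in rng.integers(4, size=n)]
    lifestyles = [LIFESTYLES[int(x)] for x in rng.integers(len(LIFESTYLES), size=n)]
    net = _finalize(species, resources, A)
    return net, _traits_frame(species, mass, families, lifestyles)


def _modular_matrix(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-block incidence matrix; returns (A, consumer blocks, resource
    blocks)."""
    n, m, B = config.n_consumers, config.n_resources, config.n_modules
    cb = np.sort(np.arange(n) % B)
    rb = np.sort(np.arange(m) % B)
    within = cb[:, None] == rb[None, :]
    p = np.where(within, config.p_in, config.p_out)
    A = (rng.random((n, m)) < p).astype(np.int8)
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        own = np.flatnonzero(rb == cb[i])
        j = int(rng.choice(own)) if own.size else int(rng.integers(m))
        A[i, j] = 1
    return A, cb, rb


def _modular_parts(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], np.ndarray, np.ndarray, TraitTable]:
    n, m, B = config.n_consumers, config.n_resources, config.n_modules
    A, cb, _ = _modular_matrix(config, rng)
    mass = 10.0 ** rng.normal(config.mass_log_mean, config.mass_log_sd, size=n)
    signature = [LIFESTYLES[b % len(LIFESTYLES)] for b in range(B)]
    lifestyles = []
    for b in cb:
        if rng.random() < config.lifestyle_fidelity:
            lifestyles.append(signature[b])
        else:
            lifestyles.append(LIFESTYLES[int(rng.integers(len(LIFESTYLES)))])
    species = _names("consumer_", n)
    resources = _names("resource_", m)
    families = [f"Fam{b}" for b in cb]
    traits = _traits_frame(species, mass, families, lifestyles)
    return species, resources, A, cb, traits


def generate_modular(config: GeneratorConfig) -> tuple[BipartiteNetwork, TraitTable]:
    """Planted-partition modular network with block-correlated lifestyles."""
    if config.n_modules < 2:
        raise ValueError("modular generator needs n_modules >= 2")
    rng = np.random.default_rng(config.seed)
    species, resources, A, _, traits = _modular_parts(config, rng)
    return _finalize(species, resources, A), traits


def generate_combined(config: GeneratorConfig) -> tuple[BipartiteNetwork, TraitTable]:
    """Modular background plus large-bodied cross-module connector
    consumers.

    Connectors (family ``ConnectorFam``) are given the largest body masses
    and strictly the highest degrees in the network, with links into every
    block — the hub role large generalist consumers play empirically.  With
    ``n_connectors=0`` the output equals ``generate_modular`` on the same
    config (same seed stream).
    """
    if config.n_modules < 2:
        raise ValueError("combined generator needs n_modules >= 2")
    rng = np.random.default_rng(config.seed)
    species, resources, A, _, traits = _modular_parts(config, rng)
    if config.n_connectors == 0:
        return _finalize(species, resources, A), traits
    n, m, B = config.n_consumers, config.n_resources, config.n_modules
    rb = np.sort(np.arange(m) % B)
    dmax = int(A.sum(axis=1).max())
    target = min(m, max(dmax + 1, B, int(round(0.35 * m))))
    rows = []
    for _ in range(config.n_connectors):
        row = np.zeros(m, dtype=np.int8)
        for b in range(B):  # at least one resource per block
            row[int(rng.choice(np.flatnonzero(rb == b)))] = 1
        extra = target - int(row.sum())
        if extra > 0:
            vacant = np.flatnonzero(row == 0)
            row[rng.choice(vacant, size=min(extra, vacant.size), replace=False)] = 1
        rows.append(row)
    A_full = np.vstack([A, np.array(rows)])
    conn_names = [f"connector_{i:02d}" for i in range(config.n_connectors)]
    # strictly heavier than every background consumer
    log_top = float(np.log10(traits.data["body_mass_g"].max()))
    conn_logmass = log_top + config.mass_log_sd * (
        0.5 + 0.5 * rng.random(config.n_connectors)
    )
    conn = pd.DataFrame(
        {
            "family": CONNECTOR_FAMILY,
            "body_mass_g": 10.0**conn_logmass,
            "lifestyle": "terrestrial",
        },
        index=pd.Index(conn_names, name="species"),
    )
    traits_full = TraitTable(pd.concat([traits.data, conn]))
    return _finalize(species + conn_names, resources, A_full), traits_full


def scaled_config(config: GeneratorConfig, n_consumers: int, n_resources: int) -> GeneratorConfig:
    """Convenience: same structure at a different size."""
    return replace(config, n_consumers=n_consumers, n_resources=n_resources)
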