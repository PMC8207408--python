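"""Reference data published for the Central Amazonian snake community
whose trophic network motivated this package.

The full 62-species x 26-resource interaction matrix is archived on Dryad
(doi:10.5061/dryad.f1vhhmgvt) and is not redistributed here; analyses of
the real community require downloading it.  What IS bundled are the small
summary tables printed in the study report: the lifestyle-by-module
contingency table of the six food modules, and the species lists used in
the targeted-removal experiments.
"""

from __future__ import annotations

from .guild_association import GuildModuleCounts
from .network_core import LIFESTYLES

__all__ = [
    "amazon_snake_guild_counts",
    "SEVEN_LARGEST",
    "BOIDAE",
]

#: The seven largest snake species of the community, removed together in
#: the targeted nestedness-robustness experiment.
SEVEN_LARGEST = (
    "Eunectes murinus",
    "Boa constrictor",
    "Lachesis muta",
    "Epicrates cenchria",
    "Corallus hortulanus",
    "Corallus caninus",
    "Spilotes pullatus",
)

#: The five boid species (family Boidae) of the community.
BOIDAE = (
    "Eunectes murinus",
    "Boa constrictor",
    "Epicrates cenchria",
    "Corallus hortulanus",
    "Corallus caninus",
)

# Module x lifestyle consumer counts for the six food modules (rows,
# modules 0-5) over the six lifestyles (columns, in LIFESTYLES order:
# aquatic, arboreal, fossorial, semi-arboreal, semi-fossorial, terrestrial).
_GUILD_COUNTS = (
    (0, 0, 10, 0, 0, 0),
    (1, 9, 0, 0, 2, 11),
    (2, 0, 3, 1, 3, 2),
    (1, 5, 0, 1, 0, 6),
    (0, 0, 0, 0, 0, 3),
    (0, 2, 0, 0, 0, 0),
)


def amazon_snake_guild_counts() -> GuildModuleCounts:
    """Published lifestyle-by-module contingency table (62 snakes, six
    food modules)."""
    return GuildModuleCounts(counts=[list(r) for r in _GUILD_COUNTS], lifestyles=LIFESTYLES)
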