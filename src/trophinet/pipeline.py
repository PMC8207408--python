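"""End-to-end analysis pipeline.

``run_pipeline`` sequences the full structural analysis on one dataset:
network assembly, connectance/degree/NODF summary, module detection,
null-model significance for nestedness and modularity, jackknife and
targeted removals, trait regressions, guild-module association, and the
secondary-resource sensitivity comparison.  Every stochastic stage derives
its own seed from the config seed, so a report is reproducible from its
recorded configuration, and all values are stored at full precision
(rounding is left to presentation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import guild_association as ga
from . import module_detection as md
from . import null_models as nm
from . import perturbation as pt
from . import structure_metrics as sm
from .network_core import BipartiteNetwork, InteractionRecord, TraitTable, build_network

logger = logging.getLogger("trophinet")

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Parameters of a full pipeline run."""

    include_secondary: bool = True
    n_null_reps: int = 1000
    n_removal_reps: int = 1000
    n_resource_removal_reps: int = 5000
    n_guild_reps: int = 1000
    n_largest_removal: int = 7  #: remove this many heaviest consumers
    removal_families: tuple[str, ...] = ()  #: families removed as groups
    schedule: md.AnnealingSchedule = field(default_factory=md.AnnealingSchedule)
    null_schedule: md.AnnealingSchedule = field(default_factory=lambda: md.FAST_SCHEDULE)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_null_reps", "n_removal_reps", "n_resource_removal_reps", "n_guild_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _seed_for(config: AnalysisConfig, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = np.random.SeedSequence([config.seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def _q_metric(schedule: md.AnnealingSchedule, seed: int):
    """Optimized-Q metric usable inside a null ensemble (degenerate
    zero-link samples score 0)."""
    counter = {"i": 0}

    def metric(A: np.ndarray) -> float:
        counter["i"] += 1
        if A.sum() < 1:
            return 0.0
        part = md.optimize_modules(A, seed=(seed + counter["i"]) % (2**31), schedule=schedule)
        return part.Q

    metric.__name__ = "optimized_barber_q"
    return metric


def run_pipeline(
    records: list[InteractionRecord],
    traits: TraitTable,
    config: AnalysisConfig | None = None,
) -> dict[str, Any]:
    """Run the whole analysis and return a JSON-serializable report."""
    config = config or AnalysisConfig()
    report: dict[str, Any] = {"config": _config_dict(config), "stages": {}}

    def stage(name: str):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)

        def done() -> None:
            dt = time.perf_counter() - t0
            report["stages"][name] = round(dt, 4)
            logger.info("stage %s finished in %.2fs", name, dt)

        return done

    done = stage("build")
    net = build_network(records, include_secondary=config.include_secondary)
    traits.check_covers(net)
    done()

    done = stage("structure")
    report["structure"] = sm.summarize(net)
    ds = sm.degree_summary(net)
    report["degrees"] = {
        "frac_low": ds.frac_low,
        "frac_high": ds.frac_high,
        "mean_degree": ds.mean_degree,
        "per_consumer": dict(zip(net.consumers, map(int, ds.consumer_degrees))),
    }
    done()

    done = stage("modules")
    part = md.optimize_modules(net, seed=_seed_for(config, "modules"), schedule=config.schedule)
    report["modularity"] = {"Q": part.Q, "n_modules": part.n_modules}
    done()

    done = stage("null_nestedness")
    nt = nm.ensemble_test(
        net, sm.nodf, n_reps=config.n_null_reps,
        seed=_seed_for(config, "null_nodf"), metric_name="nodf",
    )
    report["null_nestedness"] = dataclasses.asdict(nt)
    done()

    done = stage("null_modularity")
    qm = _q_metric(config.null_schedule, _seed_for(config, "null_q_inner"))
    mt = nm.ensemble_test(
        net, qm, n_reps=config.n_null_reps,
        seed=_seed_for(config, "null_q"), metric_name="optimized_barber_q",
    )
    report["null_modularity"] = dataclasses.asdict(mt)
    done()

    done = stage("jackknife")
    removal = pt.jackknife_nestedness(net)
    report["jackknife"] = {
        "delta_n": dict(zip(removal.species, map(float, removal.delta_n))),
    }
    on_mass, on_degree = pt.delta_regressions(removal, traits)
    report["regressions"] = {
        "degree_vs_logmass": dataclasses.asdict(pt.trait_degree_regression(net, traits)),
        "delta_n_vs_logmass": dataclasses.asdict(on_mass),
        "delta_n_vs_degree": dataclasses.asdict(on_degree),
    }
    done()

    done = stage("group_removals")
    report["group_removals"] = {}
    heaviest = sorted(net.consumers, key=traits.mass_of, reverse=True)
    groups: dict[str, list[str]] = {}
    if 0 < config.n_largest_removal < net.n_consumers:
        groups[f"largest_{config.n_largest_removal}"] = heaviest[: config.n_largest_removal]
    for fam in config.removal_families:
        members = [s for s in net.consumers if traits.family_of(s) == fam]
        if members and len(members) < net.n_consumers:
            groups[f"family_{fam}"] = members
    for name, members in groups.items():
        res = pt.group_removal_test(
            net, members, n_reps=config.n_removal_reps,
            seed=_seed_for(config, f"removal_{name}"),
        )
        report["group_removals"][name] = {
            "removed": list(res.removed),
            "observed_n": res.observed_n,
            "p_value": res.p_value,
            "pct_change": res.pct_change,
            "null_quantiles": {
                q: float(np.quantile(res.null_values, float(q)))
                for q in ("0.05", "0.5", "0.95")
            },
        }
    done()

    done = stage("guilds")
    counts = ga.tabulate_guilds(net, part, traits)
    pv = ga.guild_randomization_test(
        counts, n_reps=config.n_guild_reps, seed=_seed_for(config, "guilds")
    )
    bc = ga.bray_curtis_modules(counts)
    report["guilds"] = {
        "lifestyles": list(counts.lifestyles),
        "counts": counts.counts.tolist(),
        "p_upper": pv.p_upper.tolist(),
        "p_lower": pv.p_lower.tolist(),
        "flags": pv.flags.tolist(),
        "bray_curtis": bc.tolist(),
    }
    done()

    done = stage("sensitivity_secondary")
    has_secondary = any(r.rank == "secondary" for r in records)
    if config.include_secondary and has_secondary:
        cmp_res = pt.secondary_resource_comparison(
            records, n_reps=config.n_resource_removal_reps,
            seed=_seed_for(config, "secondary"),
        )
        report["secondary_comparison"] = dataclasses.asdict(cmp_res)
        main_net = build_network(records, include_secondary=False)
        main_nt = nm.ensemble_test(
            main_net, sm.nodf, n_reps=config.n_null_reps,
            seed=_seed_for(config, "null_nodf_main"), metric_name="nodf",
        )
        report["main_only"] = {
            "structure": sm.summarize(main_net),
            "null_nestedness": dataclasses.asdict(main_nt),
        }
    else:
        report["secondary_comparison"] = None
    done()

    return report


def _config_dict(config: AnalysisConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["removal_families"] = list(config.removal_families)
    return d


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
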