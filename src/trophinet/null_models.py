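"""Probabilistic null-model ensembles for nestedness and modularity.

The null model fills cell (i, j) independently with probability equal to
the mean of the row fill and the column fill,

    p_ij = (k_i / m + d_j / n) / 2,

so the expected number of links equals the observed F exactly while
degrees are only softly constrained.  Significance is assessed by an
add-one Monte-Carlo p-value, and the "relative" metric reports the excess
of the observed value over the null mean, scaled by that mean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np

from .network_core import BipartiteNetwork

__all__ = ["NullTestResult", "null2_probabilities", "sample_null2", "ensemble_test"]


@dataclass(frozen=True)
class NullTestResult:
    """Observed metric vs a null ensemble."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    relative: float  #: (observed - null_mean) / null_mean
    n_reps: int
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def null2_probabilities(net: BipartiteNetwork | np.ndarray) -> np.ndarray:
    """Cell fill probabilities p_ij = (k_i/m + d_j/n)/2.

    The probabilities conserve expected fill: sum(p) == F exactly.
    """
    A = net.A if isinstance(net, BipartiteNetwork) else np.asarray(net)
    n, m = A.shape
    k = A.sum(axis=1) / m
    d = A.sum(axis=0) / n
    return (k[:, None] + d[None, :]) / 2.0


def sample_null2(
    net: BipartiteNetwork | np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One binary matrix of independent Bernoulli(p_ij) draws.

    Empty rows or columns are permitted in samples; the structure metrics
    treat zero-degree entities as contributing zero, so degenerate draws
    are kept rather than resampled (resampling would bias fill upward).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = null2_probabilities(net)
    return (rng.random(p.shape) < p).astype(np.int8)


def ensemble_test(
    net: BipartiteNetwork | np.ndarray,
    metric: Callable[[np.ndarray], float],
    n_reps: int = 1000,
    seed: int | None = None,
    tail: str = "upper",
    metric_name: str | None = None,
    reference: BipartiteNetwork | np.ndarray | None = None,
) -> NullTestResult:
    """Monte-Carlo significance of ``metric(net)`` against the probabilistic
    null ensemble.

    The p-value uses the add-one correction, p = (1 + #extreme)/(1 + n_reps),
    so it is never zero; ``tail="upper"`` asks whether the observed value is
    larger than expected, ``"lower"`` smaller.  By default the null
    probabilities come from ``net`` itself; passing ``reference`` draws the
    ensemble from another network's probabilities instead (used e.g. to
    check p-value calibration under a known null).
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    A = net.A if isinstance(net, BipartiteNetwork) else np.asarray(net)
    base = A if reference is None else (
        reference.A if isinstance(reference, BipartiteNetwork) else np.asarray(reference)
    )
    observed = float(metric(A))
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_reps)
    for r in range(n_reps):
        sample = sample_null2(base, rng)
        try:
            null_vals[r] = metric(sample)
        except Exception as exc:  # pragma: no cover - degenerate samples
            raise RuntimeError(f"metric failed on null sample {r}: {exc}") from exc
    if tail == "upper":
        extreme = int(np.sum(null_vals >= observed))
    else:
        extreme = int(np.sum(null_vals <= observed))
    p = (1 + extreme) / (1 + n_reps)
    null_mean = float(null_vals.mean())
    relative = (observed - null_mean) / null_mean if null_mean != 0 else float("nan")
    return NullTestResult(
        metric=metric_name or getattr(metric, "__name__", "metric"),
        observed=observed,
        null_mean=null_mean,
        null_sd=float(null_vals.std(ddof=1)) if n_reps > 1 else 0.0,
        p_value=p,
        relative=relative,
        n_reps=n_reps,
        seed=seed if isinstance(seed, int) else None,
    )
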