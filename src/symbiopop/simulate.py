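"""Finite-population stochastic simulation of the serial-passage experiment.

Each propagation round is: FACS measurement of the positive fraction, an
optional positive sort, plating, germination, and sporulation.  All counts
are integers, all randomness flows from a single ``numpy.random.Generator``
passed explicitly, and the large-population expectation of a round reduces
to :func:`symbiopop.model.step`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .model import TransmissionParams

__all__ = [
    "SporePool",
    "SimConfig",
    "RoundRecord",
    "germinate",
    "sporulate",
    "facs_measure",
    "sort_positive",
    "plate",
    "run_passage_experiment",
    "records_to_frame",
]

# A pool this many times larger than the sample justifies replacing the
# hypergeometric draw by its binomial approximation.
_BINOMIAL_SHORTCUT_RATIO = 100


@dataclass(frozen=True)
class SporePool:
    """Finite counts of bacteria-positive and bacteria-negative spores."""

    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError(f"spore counts must be non-negative, got {self}")

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def fraction_positive(self) -> float:
        return self.n_pos / self.total if self.total else 0.0


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated serial-passage experiment.

    ``spores_per_germling`` is the per-germling spore yield ``S``; the
    experiment does not pin it down, so the default is a round 10,000 shared
    by positive and negative germlings.  ``load_effect``, when given, maps a
    per-spore bacterial load (drawn from ``load_model``) to a germination
    probability, replacing the constant ``g`` for positive spores.
    """

    n_plated: int = 100_000
    n_analyzed: int = 1_000_000
    spores_per_germling: int = 10_000
    selection_mode: Literal["positive_sort", "none"] = "none"
    sort_purity: float = 1.0
    delayed_fraction_pos: float = 0.0
    delayed_fraction_neg: float = 0.0
    load_effect: Optional[Callable[[np.ndarray], np.ndarray]] = None
    load_sampler: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_plated < 1 or self.n_analyzed < 1 or self.spores_per_germling < 1:
            raise ValueError("n_plated, n_analyzed and spores_per_germling must be >= 1")
        if self.selection_mode not in ("positive_sort", "none"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        for name in ("sort_purity", "delayed_fraction_pos", "delayed_fraction_neg"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


class FacsResult(NamedTuple):
    p_hat: float
    n_positive: int
    below_detection: bool


@dataclass(frozen=True)
class RoundRecord:
    """Observables of one simulated round."""

    line_id: str
    round: int
    n_analyzed: int
    n_positive_detected: int
    p_hat: float
    below_detection: bool
    n_plated: int
    germlings_pos: int
    germlings_neg: int
    status: str
    true_fraction: float
    below_prop: bool
    below_det: bool


def _effective_g(
    n_pos: int,
    params: TransmissionParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> float:
    """Germination probability of positive spores, optionally load-dependent.

    With a load effect, the marginal germination probability is the mean of
    ``load_effect(load)`` over per-spore loads; estimated on a Monte Carlo
    sample capped at 100,000 draws to keep large pools cheap.
    """
    if config.load_effect is None or n_pos == 0:
        return params.g
    if config.load_sampler is None:
        raise ValueError("load_effect requires a load_sampler")
    n_draw = min(n_pos, 100_000)
    loads = config.load_sampler(n_draw, rng)
    probs = np.clip(np.asarray(config.load_effect(loads), dtype=float), 0.0, 1.0)
    return float(probs.mean())


def germinate(
    pool: SporePool,
    params: TransmissionParams,
    rng: np.random.Generator,
    config: SimConfig | None = None,
) -> tuple[int, int]:
    """Draw germling counts: Binomial(n_pos, g) and Binomial(n_neg, e)."""
    g = params.g if config is None else _effective_g(pool.n_pos, params, config, rng)
    germlings_pos = int(rng.binomial(pool.n_pos, g)) if pool.n_pos else 0
    germlings_neg = int(rng.binomial(pool.n_neg, params.e)) if pool.n_neg else 0
    return germlings_pos, germlings_neg


def sporulate(
    germlings_pos: int,
    germlings_neg: int,
    p0: float,
    spores_per_germling: int,
    rng: np.random.Generator,
) -> SporePool:
    """Produce the next spore generation.

    Every germling yields ``S = spores_per_germling`` spores; each spore of
    a positive germling is independently positive with probability ``p0``,
    spores of negative germlings are all negative.  Total spore count is
    conserved: ``S * (germlings_pos + germlings_neg)``.
    """
    if germlings_pos < 0 or germlings_neg < 0:
        raise ValueError("germling counts must be non-negative")
    if spores_per_germling < 1:
        raise ValueError("spores_per_germling must be >= 1")
    n_from_pos = germlings_pos * spores_per_germling
    n_pos = int(rng.binomial(n_from_pos, p0)) if n_from_pos else 0
    n_neg = (n_from_pos - n_pos) + germlings_neg * spores_per_germling
    return SporePool(n_pos=n_pos, n_neg=n_neg)


def facs_measure(
    pool: SporePool,
    n_analyzed: int,
    rng: np.random.Generator,
) -> FacsResult:
    """Measure the positive fraction on ``n_analyzed`` spores from the pool.

    Sampling is without replacement (hypergeometric); when the pool exceeds
    100x the sample, the binomial approximation is used instead.  A sample
    with zero positives is flagged ``below_detection``.
    """
    if n_analyzed < 1:
        raise ValueError("n_analyzed must be >= 1")
    if n_analyzed > pool.total:
        raise ValueError(
            f"cannot analyse {n_analyzed} spores from a pool of {pool.total}"
        )
    if pool.n_pos == 0:
        k = 0
    elif pool.n_neg == 0:
        k = n_analyzed
    elif pool.total >= _BINOMIAL_SHORTCUT_RATIO * n_analyzed:
        k = int(rng.binomial(n_analyzed, pool.fraction_positive))
    else:
        k = int(rng.hypergeometric(pool.n_pos, pool.n_neg, n_analyzed))
    return FacsResult(p_hat=k / n_analyzed, n_positive=k, below_detection=k == 0)


def sort_positive(
    pool: SporePool,
    n_sorted: int,
    sort_purity: float,
    rng: np.random.Generator,
) -> SporePool:
    """Bulk-sort ``n_sorted`` spores through the positive gate.

    Of the sorted spores, Binomial(n_sorted, sort_purity) are truly
    positive; the remainder are negative spores mis-sorted into the gate.
    """
    if n_sorted < 0:
        raise ValueError("n_sorted must be non-negative")
    n_true_pos = int(rng.binomial(n_sorted, sort_purity)) if n_sorted else 0
    n_false = n_sorted - n_true_pos
    if n_true_pos > pool.n_pos:
        raise ValueError(
            f"sort of {n_sorted} at purity {sort_purity} needs {n_true_pos} "
            f"positive spores but the pool holds only {pool.n_pos}"
        )
    if n_false > pool.n_neg:
        raise ValueError(
            f"sort impurity requires {n_false} negative spores but the pool "
            f"holds only {pool.n_neg}"
        )
    return SporePool(n_pos=n_true_pos, n_neg=n_false)


def plate(pool: SporePool, n_plated: int, rng: np.random.Generator) -> SporePool:
    """Draw the plated subsample from the pool (all of it when smaller)."""
    if n_plated >= pool.total:
        return pool
    if pool.n_pos == 0:
        k = 0
    elif pool.n_neg == 0:
        k = n_plated
    elif pool.total >= _BINOMIAL_SHORTCUT_RATIO * n_plated:
        k = int(rng.binomial(n_plated, pool.fraction_positive))
    else:
        k = int(rng.hypergeometric(pool.n_pos, pool.n_neg, n_plated))
    return SporePool(n_pos=k, n_neg=n_plated - k)


def run_passage_experiment(
    config: SimConfig,
    params: TransmissionParams,
    p_init: float,
    n_rounds: int,
    rng: np.random.Generator,
    initial_pool: SporePool | None = None,
    line_id: str = "sim",
    param_schedule: Mapping[int, TransmissionParams] | None = None,
) -> list[RoundRecord]:
    """Run the serial-passage experiment for ``n_rounds`` passages.

    Round 0 is the initial pool; each later round measures the current pool,
    sorts positives when ``selection_mode == "positive_sort"``, plates
    ``n_plated`` spores, germinates and sporulates them.  Extinction of all
    germlings ends the run with a final ``status == "extinct"`` record.

    ``param_schedule`` optionally overrides the parameters from a given
    round onward (host adaptation is an input schedule, not a mechanism).
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    if initial_pool is None:
        if not 0.0 <= p_init <= 1.0:
            raise ValueError("p_init must be in [0, 1]")
        n_total = max(config.n_plated, config.n_analyzed)
        n_pos = int(round(p_init * n_total))
        initial_pool = SporePool(n_pos=n_pos, n_neg=n_total - n_pos)

    pool = initial_pool
    records: list[RoundRecord] = []
    for x in range(n_rounds + 1):
        if param_schedule:
            applicable = [r for r in param_schedule if r <= x]
            if applicable:
                params = param_schedule[max(applicable)]

        n_analyzed = min(config.n_analyzed, pool.total)
        measured = facs_measure(pool, n_analyzed, rng)
        true_p = pool.fraction_positive

        if x == n_rounds:
            records.append(
                _record(line_id, x, n_analyzed, measured, 0, 0, 0, "final", true_p, params)
            )
            break

        if config.selection_mode == "positive_sort":
            n_sorted = min(config.n_plated, pool.n_pos)
            plated = sort_positive(pool, n_sorted, config.sort_purity, rng)
        else:
            plated = plate(pool, config.n_plated, rng)

        germlings_pos, germlings_neg = germinate(plated, params, rng, config)
        if germlings_pos + germlings_neg == 0:
            records.append(
                _record(
                    line_id, x, n_analyzed, measured, plated.total,
                    germlings_pos, germlings_neg, "extinct", true_p, params,
                )
            )
            break

        records.append(
            _record(
                line_id, x, n_analyzed, measured, plated.total,
                germlings_pos, germlings_neg, "ok", true_p, params,
            )
        )
        pool = sporulate(
            germlings_pos, germlings_neg, params.p0, config.spores_per_germling, rng
        )
    return records


def _record(
    line_id: str,
    x: int,
    n_analyzed: int,
    measured: FacsResult,
    n_plated: int,
    germlings_pos: int,
    germlings_neg: int,
    status: str,
    true_fraction: float,
    params: TransmissionParams,
) -> RoundRecord:
    return RoundRecord(
        line_id=line_id,
        round=x,
        n_analyzed=n_analyzed,
        n_positive_detected=measured.n_positive,
        p_hat=measured.p_hat,
        below_detection=measured.below_detection,
        n_plated=n_plated,
        germlings_pos=germlings_pos,
        germlings_neg=germlings_neg,
        status=status,
        true_fraction=true_fraction,
        below_prop=true_fraction < params.t_prop,
        below_det=true_fraction < params.t_det,
    )


def records_to_frame(records: list[RoundRecord]) -> pd.DataFrame:
    """Per-round records as a data frame in the documented CSV column order."""
    columns = [
        "line_id", "round", "n_analyzed", "n_positive_detected", "p_hat",
        "below_detection", "n_plated", "germlings_pos", "germlings_neg",
        "status", "true_fraction", "below_prop", "below_det",
    ]
    frame = pd.DataFrame([r.__dict__ for r in records])
    return frame[columns] if len(frame) else pd.DataFrame(columns=columns)
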