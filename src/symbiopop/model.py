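"""Deterministic core of the vertical-transmission model.

The central object is a discrete-generation recursion for the fraction ``p``
of spores that carry endobacteria when a population is propagated *without*
selection::

    p_x = (p_{x-1} * g * p0) / (p_{x-1} * g + (1 - p_{x-1}) * e)

where ``g`` is the germination probability of bacteria-positive spores, ``e``
the germination probability of bacteria-negative spores, and ``p0`` the
transmission fidelity (fraction of spores produced by a positive germling
that are again positive).  The numerator counts positive offspring spores,
the denominator all offspring spores, both per plated spore.

This module provides the recursion itself, the fitness index, and the
analytic consequences used elsewhere: fixed points, the small-``p`` decline
factor, and the wash-out round relative to a propagation threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence, Union

__all__ = [
    "PERSISTS",
    "TransmissionParams",
    "TrajectoryEntry",
    "Trajectory",
    "StepResult",
    "FixedPoints",
    "fitness_index",
    "step",
    "step_result",
    "iterate",
    "fixed_points",
    "decline_factor",
    "washout_round",
]

#: Sentinel returned by :func:`washout_round` when the positive fraction
#: never falls below the threshold.
PERSISTS = "persists"

#: Default wash-out threshold: one positive spore expected among the
#: 100,000 spores plated per propagation round.
DEFAULT_PROPAGATION_THRESHOLD = 1e-5

#: Default detection limit of the flow-cytometric measurement
#: (one positive among 1,000,000 analysed spores).
DEFAULT_DETECTION_LIMIT = 1e-6


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if math.isnan(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TransmissionParams:
    """Parameters of the transmission recursion.

    Parameters
    ----------
    g:
        Germination probability of bacteria-positive spores, in ``[0, 1]``.
    e:
        Germination probability of bacteria-negative spores, in ``[0, 1]``.
        Defaults to 0.69, the long-term average of the negative arm of the
        evolution experiment.
    p0:
        Transmission fidelity: fraction of spores produced by a positive
        germling that carry bacteria, in ``[0, 1]``.
    t_prop:
        Wash-out threshold on the positive fraction (default ``1e-5``).
    t_det:
        Detection limit on the positive fraction (default ``1e-6``).
        Must not exceed ``t_prop``.
    """

    g: float
    e: float = 0.69
    p0: float = 0.0
    t_prop: float = DEFAULT_PROPAGATION_THRESHOLD
    t_det: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        for name in ("g", "e", "p0", "t_prop", "t_det"):
            _check_fraction(getattr(self, name), name)
        if self.t_det > self.t_prop:
            raise ValueError(
                f"detection limit t_det={self.t_det} exceeds propagation "
                f"threshold t_prop={self.t_prop}"
            )


class TrajectoryEntry(NamedTuple):
    x: int
    p: float
    below_prop: bool
    below_det: bool


@dataclass(frozen=True)
class Trajectory:
    """Ordered per-round positive fractions with threshold flags."""

    entries: tuple[TrajectoryEntry, ...]

    def __post_init__(self) -> None:
        rounds = [entry.x for entry in self.entries]
        if any(b <= a for a, b in zip(rounds, rounds[1:])):
            raise ValueError("round indices must be strictly increasing")
        for entry in self.entries:
            _check_fraction(entry.p, f"p at round {entry.x}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TrajectoryEntry]:
        return iter(self.entries)

    @property
    def rounds(self) -> tuple[int, ...]:
        return tuple(entry.x for entry in self.entries)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(entry.p for entry in self.entries)

    @classmethod
    def from_fractions(
        cls,
        fractions: Sequence[float],
        params: TransmissionParams,
        start_round: int = 0,
    ) -> "Trajectory":
        """Build a trajectory from raw fractions, flagging against thresholds.

        Flags use strict ``<`` comparison: a fraction exactly at the
        threshold counts as not washed out.
        """
        entries = tuple(
            TrajectoryEntry(
                x=start_round + i,
                p=float(p),
                below_prop=p < params.t_prop,
                below_det=p < params.t_det,
            )
            for i, p in enumerate(fractions)
        )
        return cls(entries)


def fitness_index(p: float, g: float) -> float:
    """Fitness index of the endosymbiosis: ``p * g``.

    The product of the positive fraction ``p`` and the germination success
    ``g`` of positive spores -- the expected fraction of plated spores that
    yield bacteria-containing germlings.  Commutative and confined to
    ``[0, 1]``.
    """
    p = _check_fraction(p, "p")
    g = _check_fraction(g, "g")
    return p * g


class StepResult(NamedTuple):
    p: float
    extinct: bool


def step_result(p_prev: float, params: TransmissionParams) -> StepResult:
    """One round of the recursion, reporting extinction explicitly.

    The denominator ``p*g + (1-p)*e`` is the expected germling yield per
    plated spore; when it is exactly zero no spore germinates, there is no
    next generation, and the result is ``(0.0, extinct=True)``.
    """
    p_prev = _check_fraction(p_prev, "p_prev")
    g, e, p0 = params.g, params.e, params.p0
    denominator = p_prev * g + (1.0 - p_prev) * e
    if denominator == 0.0:
        return StepResult(0.0, True)
    p_next = (p_prev * g * p0) / denominator
    # guard against rounding slightly outside [0, 1]
    return StepResult(min(max(p_next, 0.0), 1.0), False)


def step(p_prev: float, params: TransmissionParams) -> float:
    """One round of the recursion; extinction collapses to 0."""
    return step_result(p_prev, params).p


def iterate(p_init: float, params: TransmissionParams, n_rounds: int) -> Trajectory:
    """Iterate the recursion for ``n_rounds`` rounds from ``p_init``.

    The returned trajectory has ``n_rounds + 1`` entries; entry ``x=0``
    is ``p_init`` itself.
    """
    if n_rounds < 0:
        raise ValueError(f"n_rounds must be >= 0, got {n_rounds}")
    p = _check_fraction(p_init, "p_init")
    fractions = [p]
    for _ in range(int(n_rounds)):
        p = step(p, params)
        fractions.append(p)
    return Trajectory.from_fractions(fractions, params)


@dataclass(frozen=True)
class FixedPoints:
    """Fixed points of the recursion.

    ``points`` always contains 0.  When ``degenerate_all_fixed`` is true
    (``g == e`` and ``p0 == 1``) the map is the identity and *every*
    fraction is fixed; ``points`` then lists only the boundary points.
    """

    points: tuple[float, ...]
    degenerate_all_fixed: bool = False

    def __contains__(self, value: float) -> bool:
        if self.degenerate_all_fixed:
            return 0.0 <= value <= 1.0
        return any(math.isclose(value, p, rel_tol=0, abs_tol=1e-15) for p in self.points)


def fixed_points(params: TransmissionParams) -> FixedPoints:
    """Solve ``step(p) = p`` analytically.

    0 is always fixed.  For ``g != e`` the unique candidate interior fixed
    point is ``p* = (g*p0 - e) / (g - e)``, included when it lies in
    ``(0, 1]``.  For ``g == e`` the map reduces to ``p -> p * p0``, which
    is the identity iff ``p0 == 1`` (degenerate all-fixed case).
    """
    g, e, p0 = params.g, params.e, params.p0
    if g == e:
        if p0 == 1.0 and g > 0.0:
            return FixedPoints((0.0, 1.0), degenerate_all_fixed=True)
        return FixedPoints((0.0,))
    p_star = (g * p0 - e) / (g - e)
    if 0.0 < p_star <= 1.0:
        # reject algebraic solutions where the map degenerates (zero
        # denominator, e.g. p* = 1 with g = 0) or where float rounding put
        # an out-of-range solution on the boundary
        candidate = step_result(p_star, params)
        if not candidate.extinct and abs(candidate.p - p_star) < 1e-12:
            return FixedPoints((0.0, p_star))
    return FixedPoints((0.0,))


def decline_factor(params: TransmissionParams) -> float:
    """Asymptotic per-round decline factor ``lambda = g * p0 / e``.

    This is the limit of ``p_x / p_{x-1}`` as ``p -> 0``: at small positive
    fractions the recursion is geometric with this ratio.  Undefined for
    ``e == 0``.
    """
    if params.e == 0.0:
        raise ValueError("decline factor is undefined for e = 0")
    return params.g * params.p0 / params.e


def washout_round(
    p_init: float,
    params: TransmissionParams,
    threshold: float | None = None,
) -> Union[int, str]:
    """Smallest round ``x >= 0`` with ``p_x < threshold`` (strict).

    Returns :data:`PERSISTS` when the trajectory never falls below the
    threshold.  Termination is decided analytically from the trajectory's
    monotonicity and its limiting fixed point, not by an iteration cap:
    the map is monotone on [0, 1], so every orbit is monotone and converges
    to the nearest fixed point in its direction of travel.
    """
    if threshold is None:
        threshold = params.t_prop
    threshold = float(threshold)
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    p = _check_fraction(p_init, "p_init")

    if p < threshold:
        return 0

    fp = fixed_points(params)
    if fp.degenerate_all_fixed:
        # identity map: p never moves (float rounding aside)
        return PERSISTS

    first = step_result(p, params)
    if not first.extinct and first.p >= p:
        # Non-decreasing orbit: the infimum is p_init itself, >= threshold.
        return PERSISTS

    # Strictly decreasing (or extinct) orbit: its limit is the largest
    # fixed point strictly below p_init -- either p* or 0.
    limit = 0.0
    interior = [q for q in fp.points if 0.0 < q < p]
    if interior:
        limit = max(interior)
    if limit >= threshold:
        return PERSISTS

    x = 0
    while p >= threshold:
        p = step(p, params)
        x += 1
    return x
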