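"""Estimation and statistics on observed count data.

Turns round-by-round measurement tables into the quantities the analysis
reports: proportions with confidence intervals, germination success,
delayed-germination fractions, the per-line fitness index, transmission
parameters for the recursion model, log-scale model-fit error, the
mutation-frequency sweep filter, and the two significance tests used to
compare arms (Welch's unpaired t-test and the Wilcoxon matched-pairs
signed-rank test, implemented from the formulas so the exact small-sample
path is fully enumerable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .model import TransmissionParams, Trajectory, fitness_index

__all__ = [
    "RoundMeasurement",
    "ProportionEstimate",
    "ParamEstimates",
    "WelchResult",
    "WilcoxonResult",
    "estimate_proportion",
    "germination_success",
    "delayed_fraction",
    "fitness_table",
    "estimate_transmission_params",
    "model_fit_error",
    "validate_allele_table",
    "filter_sweeping_mutations",
    "sweep_fitness_correlation",
    "welch_t_test",
    "wilcoxon_signed_rank",
]

ALLELE_TABLE_COLUMNS = ("mutation_id", "round", "frequency", "present_in_ancestor")


@dataclass(frozen=True)
class RoundMeasurement:
    """One round's observable counts for one line.

    The germination arms record 96-well plate counts: ``wells_sorted`` single
    spores sorted, of which ``germinated_day1 <= germinated_day2`` produced a
    germling by day 1 and day 2.  The negative arm is optional (``None``)
    when only positive spores were plated.
    """

    line_id: str
    round: int
    facs_analyzed: int
    facs_positive: int
    wells_sorted_pos: int
    germinated_day1_pos: int
    germinated_day2_pos: int
    wells_sorted_neg: Optional[int] = None
    germinated_day1_neg: Optional[int] = None
    germinated_day2_neg: Optional[int] = None

    def __post_init__(self) -> None:
        if self.round < 0:
            raise ValueError(f"round must be non-negative, got {self.round}")
        if not 0 <= self.facs_positive <= self.facs_analyzed:
            raise ValueError(
                f"{self.line_id} round {self.round}: facs_positive "
                f"({self.facs_positive}) must be in [0, facs_analyzed="
                f"{self.facs_analyzed}]"
            )
        self._check_arm("pos", self.wells_sorted_pos,
                        self.germinated_day1_pos, self.germinated_day2_pos)
        self._check_arm("neg", self.wells_sorted_neg,
                        self.germinated_day1_neg, self.germinated_day2_neg)

    def _check_arm(self, arm: str, wells, day1, day2) -> None:
        present = [v is not None for v in (wells, day1, day2)]
        if not any(present):
            return
        if not all(present):
            raise ValueError(
                f"{self.line_id} round {self.round}: incomplete {arm} arm"
            )
        if not 0 <= day1 <= day2 <= wells:
            raise ValueError(
                f"{self.line_id} round {self.round} ({arm} arm): require "
                f"0 <= day1 ({day1}) <= day2 ({day2}) <= wells ({wells})"
            )

    @property
    def has_negative_arm(self) -> bool:
        return self.wells_sorted_neg is not None


class ProportionEstimate(NamedTuple):
    point: float
    lower: float
    upper: float


def estimate_proportion(
    k: int,
    n: int,
    method: str = "wilson",
    conf: float = 0.95,
) -> ProportionEstimate:
    """Binomial proportion with a Wilson or Clopper-Pearson interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if method not in ("wilson", "clopper_pearson"):
        raise ValueError(f"unknown method {method!r}")
    sm_method = "wilson" if method == "wilson" else "beta"
    lower, upper = proportion_confint(k, n, alpha=1.0 - conf, method=sm_method)
    point = k / n
    # float rounding in the interval formulas can land a hair outside
    # [0, 1] or on the wrong side of the point estimate; snap it back
    lower = min(max(float(lower), 0.0), point)
    upper = min(max(float(upper), point), 1.0)
    return ProportionEstimate(point=point, lower=lower, upper=upper)


def germination_success(wells_sorted: int, germinated_day2: int) -> float:
    """Fraction of sorted single spores that germinated by day 2."""
    if wells_sorted < 1:
        raise ValueError("wells_sorted must be >= 1")
    if not 0 <= germinated_day2 <= wells_sorted:
        raise ValueError(
            f"germinated_day2 ({germinated_day2}) must be in "
            f"[0, wells_sorted={wells_sorted}]"
        )
    return germinated_day2 / wells_sorted


def delayed_fraction(day1: int, day2: int) -> float:
    """Fraction of germlings first detected on day 2, of all by day 2.

    With no germlings by day 2 the quantity is undefined and NaN is
    returned (never silently 0).
    """
    if not 0 <= day1 <= day2:
        raise ValueError(f"require 0 <= day1 <= day2, got day1={day1}, day2={day2}")
    if day2 == 0:
        return math.nan
    return (day2 - day1) / day2


def fitness_table(measurements: Iterable[RoundMeasurement]) -> pd.DataFrame:
    """Per line/round table of fractions and the fitness index.

    The fitness index is the composition of the positive-fraction point
    estimate with the positive-arm germination success via
    :func:`symbiopop.model.fitness_index`; no quantity is recomputed by a
    second path.  Rows lacking the negative arm carry NaN there and are
    flagged in ``missing_neg_arm``.
    """
    rows = []
    for m in measurements:
        p = estimate_proportion(m.facs_positive, m.facs_analyzed).point
        g_pos = germination_success(m.wells_sorted_pos, m.germinated_day2_pos)
        delayed_pos = delayed_fraction(m.germinated_day1_pos, m.germinated_day2_pos)
        if m.has_negative_arm:
            g_neg = germination_success(m.wells_sorted_neg, m.germinated_day2_neg)
            delayed_neg = delayed_fraction(m.germinated_day1_neg, m.germinated_day2_neg)
        else:
            g_neg = math.nan
            delayed_neg = math.nan
        rows.append({
            "line_id": m.line_id,
            "round": m.round,
            "positive_fraction": p,
            "germination_pos": g_pos,
            "germination_neg": g_neg,
            "fitness_index": fitness_index(p, g_pos),
            "delayed_pos": delayed_pos,
            "delayed_neg": delayed_neg,
            "missing_neg_arm": not m.has_negative_arm,
        })
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(["line_id", "round"], kind="stable")
        frame = frame.reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class ParamEstimates:
    """Transmission parameters estimated from a round-0 measurement."""

    params: TransmissionParams
    g_interval: ProportionEstimate
    p0_interval: ProportionEstimate
    e_interval: Optional[ProportionEstimate]
    e_is_fallback: bool


def estimate_transmission_params(
    round0: RoundMeasurement,
    fallback_e: float = 0.69,
    conf: float = 0.95,
) -> ParamEstimates:
    """Estimate (g, e, p0) from the starting-point measurement.

    ``g`` is the positive-arm germination success, ``e`` the negative-arm
    germination success (or ``fallback_e``, the long-term experiment average,
    when that arm is absent), and ``p0`` the measured positive fraction,
    which the model reuses both as initial condition and as transmission
    fidelity.  Wilson intervals accompany every estimated proportion.
    """
    if round0.wells_sorted_pos < 1:
        raise ValueError("round 0 must include a positive germination arm")
    g_ci = estimate_proportion(
        round0.germinated_day2_pos, round0.wells_sorted_pos, conf=conf
    )
    p0_ci = estimate_proportion(round0.facs_positive, round0.facs_analyzed, conf=conf)
    if round0.has_negative_arm and round0.wells_sorted_neg >= 1:
        e_ci = estimate_proportion(
            round0.germinated_day2_neg, round0.wells_sorted_neg, conf=conf
        )
        e_point, fallback = e_ci.point, False
    else:
        e_ci, e_point, fallback = None, fallback_e, True
    params = TransmissionParams(g=g_ci.point, e=e_point, p0=p0_ci.point)
    return ParamEstimates(
        params=params,
        g_interval=g_ci,
        p0_interval=p0_ci,
        e_interval=e_ci,
        e_is_fallback=fallback,
    )


def model_fit_error(observed: Trajectory, predicted: Trajectory) -> float:
    """Root-mean-square error of log10 positive fractions.

    Observations below the detection limit (flagged or measured as zero)
    are censored and excluded.  Raises when the round indices differ or no
    comparable round remains.
    """
    if observed.rounds != predicted.rounds:
        raise ValueError(
            f"round indices differ: observed {observed.rounds} vs "
            f"predicted {predicted.rounds}"
        )
    residuals = []
    for obs, pred in zip(observed, predicted):
        if obs.below_det or obs.p <= 0.0 or pred.p <= 0.0:
            continue
        residuals.append(math.log10(obs.p) - math.log10(pred.p))
    if not residuals:
        raise ValueError("no comparable (non-censored, positive) rounds")
    return float(np.sqrt(np.mean(np.square(residuals))))


def validate_allele_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the allele-frequency table schema and value ranges."""
    missing = [c for c in ALLELE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele table missing columns: {missing}")
    freq = table["frequency"].to_numpy(dtype=float)
    if len(freq) and (np.nanmin(freq) < 0.0 or np.nanmax(freq) > 1.0):
        raise ValueError("allele frequencies must be fractions in [0, 1]")
    return table


def filter_sweeping_mutations(table: pd.DataFrame, min_freq: float = 0.5) -> list[str]:
    """Mutations absent in the ancestor whose peak frequency reaches min_freq.

    The threshold is inclusive ("at least"): a peak of exactly ``min_freq``
    is retained.  Returns sorted mutation ids.
    """
    validate_allele_table(table)
    if not len(table):
        return []
    novel = table[~table["present_in_ancestor"].astype(bool)]
    peaks = novel.groupby("mutation_id")["frequency"].max()
    return sorted(peaks.index[peaks >= min_freq].tolist())


def sweep_fitness_correlation(
    freqs: Sequence[float],
    fitness: Sequence[float],
) -> float:
    """Spearman rank correlation between an allele-frequency series and the
    per-round fitness-index series.  NaN when either series is constant
    (ranks undefined)."""
    freqs = np.asarray(freqs, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    if freqs.shape != fitness.shape:
        raise ValueError("series must have equal length")
    if len(freqs) < 3:
        raise ValueError("need at least 3 rounds")
    if np.ptp(freqs) == 0.0 or np.ptp(fitness) == 0.0:
        return math.nan
    rho = stats.spearmanr(freqs, fitness).statistic
    return float(rho)


class WelchResult(NamedTuple):
    t: float
    df: float
    pvalue: float


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided unpaired t-test with Welch's correction.

    Implemented from the formulas: ``t = (mx - my) / sqrt(vx/nx + vy/ny)``
    with Welch-Satterthwaite degrees of freedom.  Returns NaNs when both
    samples have zero variance (statistic undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return WelchResult(math.nan, math.nan, math.nan)
    sx, sy = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


class WilcoxonResult(NamedTuple):
    w: float
    pvalue: float
    n_used: int
    exact: bool


def _signed_rank_exact_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for the signed-rank statistic under the null.

    Enumerates the 2^n equiprobable sign assignments via the generating
    polynomial of the rank sums.  Midranks (ties) are multiples of 1/2, so
    doubling makes all sums integral.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_pos * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact_when_n_le: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    ``x`` holds paired differences, or the first arm when ``y`` is given.
    Zero differences are dropped (standard convention).  For ``n`` retained
    differences up to ``exact_when_n_le`` the p-value is exact over all
    2^n sign assignments; beyond that a normal approximation with tie
    correction and continuity correction is used.  The reported statistic
    ``W`` is the sum of ranks of positive differences.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(math.nan, math.nan, 0, False)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_when_n_le:
        p = _signed_rank_exact_p(ranks, w_pos)
        return WilcoxonResult(w_pos, p, n, True)
    mean = n * (n + 1) / 4.0
    # tie correction: sum over tie groups of (t^3 - t) / 48
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0.0:
        return WilcoxonResult(w_pos, math.nan, n, False)
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(w_pos, float(min(p, 1.0)), n, False)
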