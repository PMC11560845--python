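"""Synthetic-data generation from known ground truth.

Everything the pipeline consumes can be generated here: round-by-round
measurement tables following the serial-passage design (10 lines seeded
with ~300 positive spores, 100,000 plated per round, pooling of the
non-elite lines after round 7), allele-frequency sweep tables, per-spore
FACS intensity lists, and 3D spore image stacks with constructed voxel
ground truth.  Truth manifests are kept separate from the data files so
downstream estimation can be run blind.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as table_io
from .imaging import VoxelStack
from .inference import ALLELE_TABLE_COLUMNS, RoundMeasurement
from .model import TransmissionParams
from .simulate import (
    SimConfig,
    SporePool,
    germinate,
    plate,
    sort_positive,
    sporulate,
)

__all__ = [
    "LoadModel",
    "SweepSpec",
    "TruthConfig",
    "generate_round_measurement",
    "generate_experiment",
    "generate_sweep_table",
    "generate_spore_stack",
    "generate_facs_intensities",
    "write_experiment",
]

POOLED_LINE_ID = "P"


@dataclass(frozen=True)
class LoadModel:
    """Lognormal model of per-spore bacterial load and its FACS intensity.

    ``median``/``sigma`` parameterise the lognormal load of positive spores
    (load in µm³); total intensity is ``baseline + intensity_factor * load``
    on top of autofluorescence noise shared with negative spores.
    """

    median: float = 2.0
    sigma: float = 0.6
    intensity_factor: float = 1000.0
    baseline: float = 100.0
    baseline_sd: float = 10.0

    def sample_loads(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(mean=math.log(self.median), sigma=self.sigma, size=n)


@dataclass(frozen=True)
class SweepSpec:
    """Logistic allele-frequency trajectory of one sweeping mutation."""

    mutation_id: str
    selection: float = 1.5
    appear_round: int = 5
    init_freq: float = 0.02
    present_in_ancestor: bool = False

    def frequency(self, round_index: int) -> float:
        if round_index < self.appear_round:
            return 0.0
        odds0 = self.init_freq / (1.0 - self.init_freq)
        logit = math.log(odds0) + self.selection * (round_index - self.appear_round)
        return 1.0 / (1.0 + math.exp(-logit))


@dataclass(frozen=True)
class TruthConfig:
    """Ground truth and design of a synthetic serial-passage experiment."""

    params: TransmissionParams
    p_init: float = 1e-4
    n_lines: int = 10
    n_rounds: int = 10
    round1_spores_per_line: int = 300
    n_plated: int = 100_000
    n_analyzed: int = 1_000_000
    spores_per_germling: int = 10_000
    pool_after_round: Optional[int] = 7
    n_kept_lines: int = 3
    wells_pos: int = 288
    wells_neg: int = 96
    delayed_fraction_pos: float = 0.3
    delayed_fraction_neg: float = 0.05
    sort_purity: float = 1.0
    param_schedule: Optional[Mapping[int, TransmissionParams]] = None
    load_model: LoadModel = field(default_factory=LoadModel)
    sweeps: tuple[SweepSpec, ...] = ()
    # optional multiplicative decay of g per day of spore storage
    aging_rate_per_day: float = 0.0
    storage_days: float = 0.0
    seed: int = 0

    def params_at(self, round_index: int) -> TransmissionParams:
        params = self.params
        if self.param_schedule:
            applicable = [r for r in self.param_schedule if r <= round_index]
            if applicable:
                params = self.param_schedule[max(applicable)]
        if self.aging_rate_per_day > 0.0 and self.storage_days > 0.0:
            decayed_g = params.g * math.exp(-self.aging_rate_per_day * self.storage_days)
            params = dataclasses.replace(params, g=decayed_g)
        return params

    def to_manifest(self) -> dict:
        manifest = dataclasses.asdict(self)
        manifest["param_schedule"] = (
            {str(k): dataclasses.asdict(v) for k, v in self.param_schedule.items()}
            if self.param_schedule
            else None
        )
        return manifest


def generate_round_measurement(
    line_id: str,
    round_index: int,
    true_p: float,
    params: TransmissionParams,
    rng: np.random.Generator,
    n_analyzed: int = 1_000_000,
    wells_pos: int = 288,
    wells_neg: Optional[int] = 96,
    delayed_fraction_pos: float = 0.0,
    delayed_fraction_neg: float = 0.0,
) -> RoundMeasurement:
    """Draw one round's observable counts at a known true positive fraction.

    FACS positives are Binomial(n_analyzed, true_p); each germination arm is
    Binomial(wells, germination probability), with day-1 counts thinned by
    the delayed fraction.
    """
    facs_positive = int(rng.binomial(n_analyzed, true_p))
    day2_pos = int(rng.binomial(wells_pos, params.g)) if true_p > 0 else 0
    day1_pos = day2_pos - int(rng.binomial(day2_pos, delayed_fraction_pos))
    kwargs: dict = {}
    if wells_neg is not None:
        day2_neg = int(rng.binomial(wells_neg, params.e))
        day1_neg = day2_neg - int(rng.binomial(day2_neg, delayed_fraction_neg))
        kwargs = dict(
            wells_sorted_neg=wells_neg,
            germinated_day1_neg=day1_neg,
            germinated_day2_neg=day2_neg,
        )
    return RoundMeasurement(
        line_id=line_id,
        round=round_index,
        facs_analyzed=n_analyzed,
        facs_positive=facs_positive,
        wells_sorted_pos=wells_pos,
        germinated_day1_pos=day1_pos,
        germinated_day2_pos=day2_pos,
        **kwargs,
    )


def _advance_line(
    pool: SporePool,
    truth: TruthConfig,
    params: TransmissionParams,
    rng: np.random.Generator,
) -> SporePool:
    """One passage: sort positives (plating unsorted when none exist),
    plate, germinate, sporulate."""
    config = SimConfig(
        n_plated=truth.n_plated,
        n_analyzed=truth.n_analyzed,
        spores_per_germling=truth.spores_per_germling,
        selection_mode="positive_sort",
        sort_purity=truth.sort_purity,
    )
    if pool.n_pos > 0:
        n_sorted = min(truth.n_plated, pool.n_pos)
        plated = sort_positive(pool, n_sorted, truth.sort_purity, rng)
    else:
        plated = plate(pool, truth.n_plated, rng)
    germlings_pos, germlings_neg = germinate(plated, params, rng, config)
    if germlings_pos + germlings_neg == 0:
        return SporePool(0, 0)
    return sporulate(
        germlings_pos, germlings_neg, params.p0, truth.spores_per_germling, rng
    )


def generate_experiment(
    truth: TruthConfig,
) -> tuple[list[RoundMeasurement], pd.DataFrame, dict]:
    """Generate a full synthetic evolution experiment.

    Returns the measurement rows (inference CSV schema), the allele-frequency
    sweep table, and a run manifest holding the seed and the ground truth.
    Lines start at round 1 from ``round1_spores_per_line`` sorted positive
    spores; round-1 FACS reflects the pre-sort plate fraction ``p_init``.
    After ``pool_after_round``, the ``n_kept_lines`` best lines by measured
    fitness index continue individually and the rest merge into line "P".
    """
    rng = np.random.default_rng(truth.seed)
    measurements: list[RoundMeasurement] = []

    pools: dict[str, SporePool] = {
        f"L{i + 1}": SporePool(truth.round1_spores_per_line, 0)
        for i in range(truth.n_lines)
    }

    for round_index in range(1, truth.n_rounds + 1):
        params = truth.params_at(round_index)
        round_measurements: dict[str, RoundMeasurement] = {}
        for line_id in sorted(pools):
            pool = pools[line_id]
            if pool.total == 0:
                continue  # extinct line
            if round_index == 1:
                true_p = truth.p_init
            else:
                true_p = pool.fraction_positive
            m = generate_round_measurement(
                line_id,
                round_index,
                true_p,
                params,
                rng,
                n_analyzed=truth.n_analyzed,
                wells_pos=truth.wells_pos,
                wells_neg=truth.wells_neg,
                delayed_fraction_pos=truth.delayed_fraction_pos,
                delayed_fraction_neg=truth.delayed_fraction_neg,
            )
            round_measurements[line_id] = m
            measurements.append(m)
            pools[line_id] = _advance_line(pool, truth, params, rng)

        if truth.pool_after_round is not None and round_index == truth.pool_after_round:
            pools = _apply_pooling(pools, round_measurements, truth)

    allele_table = generate_sweep_table(truth)
    manifest = {
        "seed": truth.seed,
        "truth": truth.to_manifest(),
        "n_measurement_rows": len(measurements),
    }
    return measurements, allele_table, manifest


def _apply_pooling(
    pools: dict[str, SporePool],
    round_measurements: dict[str, RoundMeasurement],
    truth: TruthConfig,
) -> dict[str, SporePool]:
    """Keep the best lines by measured fitness index; merge the rest."""

    def measured_fitness(line_id: str) -> float:
        m = round_measurements.get(line_id)
        if m is None or m.wells_sorted_pos == 0:
            return -1.0
        p = m.facs_positive / m.facs_analyzed
        g = m.germinated_day2_pos / m.wells_sorted_pos
        return p * g

    alive = [lid for lid, pool in pools.items() if pool.total > 0]
    ranked = sorted(alive, key=lambda lid: (-measured_fitness(lid), lid))
    kept = set(ranked[: truth.n_kept_lines])
    merged_pos = sum(pools[lid].n_pos for lid in alive if lid not in kept)
    merged_neg = sum(pools[lid].n_neg for lid in alive if lid not in kept)
    new_pools = {lid: pools[lid] for lid in kept}
    if merged_pos + merged_neg > 0:
        new_pools[POOLED_LINE_ID] = SporePool(merged_pos, merged_neg)
    return new_pools


def generate_sweep_table(truth: TruthConfig) -> pd.DataFrame:
    """Deterministic logistic allele-frequency trajectories per round."""
    rows = []
    for sweep in truth.sweeps:
        for round_index in range(1, truth.n_rounds + 1):
            rows.append({
                "mutation_id": sweep.mutation_id,
                "round": round_index,
                "frequency": sweep.frequency(round_index),
                "present_in_ancestor": sweep.present_in_ancestor,
            })
    return pd.DataFrame(rows, columns=list(ALLELE_TABLE_COLUMNS))


def generate_spore_stack(
    n_bacteria: int,
    shape: tuple[int, int, int] = (32, 64, 64),
    voxel_dims: tuple[float, float, float] = (0.2, 0.1, 0.1),
    psf_sigma: float = 0.0,
    background: float = 10.0,
    signal: float = 200.0,
    poisson_noise: bool = False,
    gauss_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[VoxelStack, int]:
    """Render a synthetic spore z-stack with rod-shaped bacteria.

    Rods of roughly 0.5 x 0.5 x 2 µm are placed without overlap inside an
    ellipsoidal spore mask, optionally blurred (``psf_sigma`` in voxel
    units) and corrupted with Poisson and Gaussian noise.  Returns the stack
    and the ground-truth count of above-background voxels of the noiseless
    image (for zero blur this is exactly the constructed rod voxel count).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_bacteria < 0:
        raise ValueError("n_bacteria must be non-negative")
    shape = tuple(int(s) for s in shape)
    dz, dy, dx = (float(d) for d in voxel_dims)

    zc, yc, xc = ((s - 1) / 2.0 for s in shape)
    zr, yr, xr = (0.42 * s for s in shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    spore_mask = (
        ((zz - zc) / zr) ** 2 + ((yy - yc) / yr) ** 2 + ((xx - xc) / xr) ** 2
    ) <= 1.0

    rod_extent = {
        "y": (max(1, round(0.5 / dz)), max(1, round(2.0 / dy)), max(1, round(0.5 / dx))),
        "x": (max(1, round(0.5 / dz)), max(1, round(0.5 / dy)), max(1, round(2.0 / dx))),
    }
    rod_extent = {
        axis: ext
        for axis, ext in rod_extent.items()
        if all(e <= s for e, s in zip(ext, shape))
    }
    if n_bacteria > 0 and not rod_extent:
        raise ValueError(
            f"no rod orientation fits a stack of shape {shape}: geometry overcrowded"
        )
    orientations = sorted(rod_extent)
    signal_mask = np.zeros(shape, dtype=bool)
    for _ in range(n_bacteria):
        placed = False
        for _attempt in range(200):
            axis = orientations[int(rng.integers(len(orientations)))]
            ez, ey, ex = rod_extent[axis]
            z0 = rng.integers(0, shape[0] - ez + 1)
            y0 = rng.integers(0, shape[1] - ey + 1)
            x0 = rng.integers(0, shape[2] - ex + 1)
            region = (slice(z0, z0 + ez), slice(y0, y0 + ey), slice(x0, x0 + ex))
            if not spore_mask[region].all():
                continue
            if signal_mask[region].any():
                continue
            signal_mask[region] = True
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place {n_bacteria} bacteria in a stack of shape "
                f"{shape}: geometry overcrowded"
            )

    clean = np.full(shape, background, dtype=float)
    clean[signal_mask] = signal
    if psf_sigma > 0.0:
        clean = gaussian_filter(clean, sigma=psf_sigma)
    truth_voxels = int((clean > background + 0.25 * (signal - background)).sum())
    if psf_sigma == 0.0:
        truth_voxels = int(signal_mask.sum())

    noisy = clean
    if poisson_noise:
        noisy = rng.poisson(np.clip(noisy, 0.0, None)).astype(float)
    if gauss_sd > 0.0:
        noisy = noisy + rng.normal(0.0, gauss_sd, size=shape)
    noisy = np.clip(noisy, 0.0, None)
    return VoxelStack(noisy, (dz, dy, dx)), truth_voxels


def generate_facs_intensities(
    pool: SporePool,
    load_model: LoadModel,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-spore total fluorescence intensities with true labels.

    Positive spores get ``autofluorescence + intensity_factor * load`` with
    lognormal loads; negative spores get autofluorescence only.  Returns
    (intensities, is_positive, loads) with loads zero for negatives.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = pool.total
    labels = np.zeros(n, dtype=bool)
    labels[: pool.n_pos] = True
    auto = np.clip(
        rng.normal(load_model.baseline, load_model.baseline_sd, size=n), 0.0, None
    )
    loads = np.zeros(n, dtype=float)
    if pool.n_pos:
        loads[: pool.n_pos] = load_model.sample_loads(pool.n_pos, rng)
    intensities = auto + load_model.intensity_factor * loads
    return intensities, labels, loads


def write_experiment(
    truth: TruthConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Generate and write measurements.csv, alleles.csv and manifest.json.

    The manifest (holding the ground truth) is a separate file from the
    data tables, so estimation can be run blind to truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    measurements, alleles, manifest = generate_experiment(truth)
    cfg_hash = table_io.config_hash(manifest["truth"])
    provenance = {"config_sha256": cfg_hash, "seed": truth.seed}
    paths = {
        "measurements": out_dir / "measurements.csv",
        "alleles": out_dir / "alleles.csv",
        "manifest": out_dir / "manifest.json",
    }
    table_io.write_measurement_table(measurements, paths["measurements"], provenance)
    table_io.write_allele_table(alleles, paths["alleles"], provenance)
    table_io.write_manifest({**manifest, "config_sha256": cfg_hash}, paths["manifest"])
    return paths
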