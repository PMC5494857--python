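"""Regime-labelled synthetic plates with ground truth.

Trajectories are generated from the extended sigmoid itself — the model
class the estimator assumes — on a BioLector-like grid of 448 points at a
6-minute cycle (0–44.7 h), with multiplicative Gaussian noise (scattered-
light noise scales with intensity). Each induced culture draws its
dimensionless targets (c_std, slope_std) uniformly from a regime box that
is strictly interior to the corresponding decision region, so a perfect
pipeline would classify every culture back into its generating regime:

* insufficient — near-uninduced growth: c_std ∈ [0.80, 1.05],
  slope_std ∈ [0.60, 1.40], full hub;
* optimal — quasi-linear rise: c_std ∈ [1.15, 1.85],
  slope_std ∈ [0.05, 0.24], hub reduced to 60% of the reference (strong
  expressers form less biomass);
* too strong — extended lag, late rise: c_std ∈ [2.05, 3.50],
  slope_std ∈ [0.30, 1.20], full hub.

The drawn targets are realized exactly: c = c_std·c_ref and d is solved
from slope_std·slope_ref = b/(4·d) + e with b and e held at their
regime-consistent values. True EP is the default response-surface value
at the drawn targets clipped to [0, 1]; observed EP adds Gaussian noise.
Each well gets an independent substream keyed by (seed, well index), so
adding wells never perturbs earlier wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from inductionscope.errors import RegimeConfigError
from inductionscope.induction_model import EPModel, StandardizedFeatures, predict_ep
from inductionscope.plate_io import CultureMetadata, CultureRecord, PlateDataset
from inductionscope.sigmoid_fit import SigmoidParams, extended_sigmoid, slope_at_inflection

REGIMES = ("reference", "insufficient", "optimal", "too_strong")

#: fraction of the reference hub realized per regime
HUB_FACTORS = {"reference": 1.0, "insufficient": 1.0, "optimal": 0.6, "too_strong": 1.0}

#: nominal inducer concentration [uM] written to the metadata per regime
INDUCER_CONC = {"reference": 0.0, "insufficient": 10.0, "optimal": 100.0, "too_strong": 1000.0}

DEFAULT_INDUCTION_TIME_H = 6.0


def default_grid() -> np.ndarray:
    """448 measurement points at a 6-minute cycle: 0, 0.1, …, 44.7 h."""
    return np.arange(448) * 0.1


@dataclass
class RegimeSpec:
    """One regime's target box in (c_std, slope_std) and its culture count."""

    regime: str
    c_std_range: tuple[float, float]
    slope_std_range: tuple[float, float]
    n_cultures: int

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise RegimeConfigError(f"unknown regime {self.regime!r}")
        for lo, hi in (self.c_std_range, self.slope_std_range):
            if not lo <= hi:
                raise RegimeConfigError(f"invalid range ({lo}, {hi}) in regime {self.regime}")
        if self.n_cultures < 0:
            raise RegimeConfigError("n_cultures must be >= 0")


def default_regimes(n_per_regime: int = 50, n_reference: int = 1) -> list[RegimeSpec]:
    """The standard study conditions: boxes interior to the rule regions."""
    return [
        RegimeSpec("reference", (1.0, 1.0), (1.0, 1.0), n_reference),
        RegimeSpec("insufficient", (0.80, 1.05), (0.60, 1.40), n_per_regime),
        RegimeSpec("optimal", (1.15, 1.85), (0.05, 0.24), n_per_regime),
        RegimeSpec("too_strong", (2.05, 3.50), (0.30, 1.20), n_per_regime),
    ]


@dataclass
class PlateSimConfig:
    """Full simulation configuration; defaults are the study conditions."""

    regimes: list[RegimeSpec] = field(default_factory=default_regimes)
    reference_params: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(a=2.0, b=40.0, c=15.0, d=2.0, e=0.2)
    )
    grid: np.ndarray = field(default_factory=default_grid)
    noise_cv: float = 0.02
    ep_noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.noise_cv < 0 or self.ep_noise_sd < 0:
            raise RegimeConfigError("noise levels must be >= 0")
        if np.any(np.diff(self.grid) <= 0):
            raise RegimeConfigError("grid must be strictly increasing")


def default_config(seed: int = 0, n_per_regime: int = 50, n_reference: int = 1) -> PlateSimConfig:
    return PlateSimConfig(regimes=default_regimes(n_per_regime, n_reference), seed=seed)


@dataclass
class GroundTruthRow:
    """Generating parameters and EP of one simulated culture."""

    well: str
    regime: str
    true_params: SigmoidParams
    true_c_std: float
    true_slope_std: float
    true_ep: float
    observed_ep: float


def _params_for_targets(
    regime: str, c_std: float, slope_std: float, ref: SigmoidParams
) -> SigmoidParams:
    """Realize (c_std, slope_std) exactly within the regime's parameter family."""
    b = HUB_FACTORS[regime] * ref.b
    e = ref.e
    slope_ref = slope_at_inflection(ref)
    target = slope_std * slope_ref
    if target <= e:
        raise RegimeConfigError(
            f"{regime}: target inflection slope {target:.4g} a.u./h is not above the "
            f"linear slope e={e:.4g}; d has no positive solution"
        )
    return SigmoidParams(a=ref.a, b=b, c=c_std * ref.c, d=b / (4.0 * (target - e)), e=e)


def simulate_culture(
    regime: RegimeSpec,
    config: PlateSimConfig,
    rng: np.random.Generator,
    plate_id: str = "SIM01",
    well_id: str = "A01",
) -> tuple[CultureRecord, GroundTruthRow]:
    """Draw one culture from a regime box and synthesize its trajectory."""
    c_std = float(rng.uniform(*regime.c_std_range))
    slope_std = float(rng.uniform(*regime.slope_std_range))
    params = _params_for_targets(regime.regime, c_std, slope_std, config.reference_params)
    clean = extended_sigmoid(config.grid, params)
    signal = clean * (1.0 + rng.normal(0.0, config.noise_cv, size=config.grid.size))
    signal = np.maximum(signal, 0.0)
    true_ep = predict_ep(
        StandardizedFeatures(c_std=c_std, slope_std=slope_std, source_well=well_id)
    ).clipped
    observed_ep = float(true_ep + rng.normal(0.0, config.ep_noise_sd))
    is_ref = regime.regime == "reference"
    metadata = CultureMetadata(
        plate_id=plate_id,
        well_id=well_id,
        strain="E. coli simulated",
        product="synthetic",
        temperature=30.0,
        inducer_conc=INDUCER_CONC[regime.regime],
        induction_time=None if is_ref else DEFAULT_INDUCTION_TIME_H,
        induced=not is_ref,
        is_reference=is_ref,
        mtp_format="well96",
        device_id="simulator",
    )
    record = CultureRecord(
        metadata=metadata,
        times=config.grid.copy(),
        scattered_light=signal,
        final_expression=observed_ep,
    )
    truth = GroundTruthRow(
        well=f"{plate_id}/{well_id}",
        regime=regime.regime,
        true_params=params,
        true_c_std=c_std,
        true_slope_std=slope_std,
        true_ep=true_ep,
        observed_ep=observed_ep,
    )
    return record, truth


def _well_name(index: int) -> tuple[str, str]:
    """Deterministic plate/well naming over 96-well plates: A01…H12."""
    plate = index // 96
    pos = index % 96
    row, col = divmod(pos, 12)
    return f"SIM{plate + 1:02d}", f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_plate(config: PlateSimConfig) -> tuple[PlateDataset, list[GroundTruthRow]]:
    """Simulate all configured regimes into one validated dataset.

    Wells are named deterministically in configuration order; each well's
    randomness comes from its own (seed, index)-keyed substream, so the
    same seed reproduces the plate bit for bit and appending regimes never
    changes existing wells.
    """
    total = sum(r.n_cultures for r in config.regimes)
    if total < 1:
        raise RegimeConfigError("at least one culture must be requested")
    any_induced = any(r.regime != "reference" and r.n_cultures > 0 for r in config.regimes)
    any_reference = any(r.regime == "reference" and r.n_cultures > 0 for r in config.regimes)
    if any_induced and not any_reference:
        raise RegimeConfigError("induced regimes require at least one reference culture")

    cultures: list[CultureRecord] = []
    truths: list[GroundTruthRow] = []
    index = 0
    for regime in config.regimes:
        for _ in range(regime.n_cultures):
            rng = np.random.default_rng([config.seed, index])
            plate_id, well_id = _well_name(index)
            record, truth = simulate_culture(regime, config, rng, plate_id, well_id)
            cultures.append(record)
            truths.append(truth)
            index += 1
    dataset = PlateDataset(cultures=cultures, dataset_id=f"synthetic-seed{config.seed}")
    return dataset, truths
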