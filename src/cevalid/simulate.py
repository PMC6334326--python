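"""Synthetic electropherogram generation with known ground truth.

Every study the validation pipeline consumes — calibration series, system
suitability replicates, robustness runs, degraded samples — can be generated
here under a configurable response law, so each downstream statistic can be
checked against the truth that produced its input.

The analyte peak is a single Gaussian on a linearly drifting baseline with
i.i.d. Gaussian detector noise.  The response law is imposed on the
*corrected* peak area (raw area divided by migration time, the CE
quantitation variable): the target corrected area of a run at concentration
``C`` is ``slope·C + intercept`` plus area noise, and the Gaussian is scaled
so that its raw area equals that target times the actual apex time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .config import RobustnessStudySpec, SimulationConfig

_LN10 = np.log(10.0)

#: instrument conditions attached as metadata to every simulated run; these
#: are descriptive tags (the robustness factor labels), not physics inputs.
NOMINAL_CONDITIONS = {
    "buffer_mm": 10.0,
    "buffer_ph": 7.0,
    "voltage_kv": 15.0,
    "wavelength_nm": 214.0,
    "injection_s": 5.0,
    "cartridge_temp_c": 25.0,
}


@dataclass
class Electropherogram:
    """A uniformly sampled detector time-series plus run metadata."""

    time: np.ndarray  # minutes, strictly increasing uniform grid
    signal: np.ndarray  # mAU
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise ValueError("time and signal must be finite")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class SpeciesProfile:
    """Protonation-state fractions of a polyprotic analyte across a pH grid."""

    pkas: np.ndarray  # ascending macroscopic dissociation constants
    ph_grid: np.ndarray
    fractions: np.ndarray  # (n_ph, n_pkas + 1), most-protonated state first


def _subseeds(master: int, n: int) -> np.ndarray:
    """Deterministic per-run seeds derived from one master seed."""
    return np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)


def _simulate_run(
    config: SimulationConfig,
    concentration: float,
    seed: int,
    area_scale: float = 1.0,
    label: str = "sample",
    conditions: dict | None = None,
) -> Electropherogram:
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    # draw in a fixed order so runs differing only in area_scale share noise
    area_noise = rng.normal(0.0, config.noise_sd) if config.noise_sd >= 0 else 0.0
    jitter = rng.normal(0.0, config.migration_jitter_sd)
    target_area = config.response_slope * concentration + config.response_intercept + area_noise
    if target_area <= 0:
        raise ValueError(
            f"non-positive target corrected area at {concentration} µg/mL; "
            "increase the concentration or reduce the noise level"
        )
    target_area *= area_scale
    apex = config.migration_time + jitter

    n = int(round(config.run_length * config.sampling_rate)) + 1
    t = np.arange(n) / config.sampling_rate
    raw_area = target_area * apex
    height = raw_area / (config.peak_sigma * np.sqrt(2.0 * np.pi))
    peak = height * np.exp(-0.5 * ((t - apex) / config.peak_sigma) ** 2)
    baseline = config.baseline_level + config.baseline_drift_slope * t
    noise = rng.normal(0.0, config.baseline_noise_sd, size=n)
    meta = {
        "sample_label": label,
        "nominal_conc_ug_ml": float(concentration),
        "true_corrected_area": float(target_area),
        "true_apex_min": float(apex),
        "seed": int(seed),
        "conditions": dict(conditions if conditions is not None else NOMINAL_CONDITIONS),
    }
    return Electropherogram(time=t, signal=baseline + peak + noise, metadata=meta)


def simulate_electropherogram(
    config: SimulationConfig, concentration: float, seed: int
) -> Electropherogram:
    """Simulate one run at the given concentration.

    The run contains one Gaussian analyte peak centred at
    ``migration_time + jitter`` whose raw area equals the (noisy) target
    corrected area times the actual apex time, on a drifting noisy baseline.
    Ground-truth values are recorded in ``metadata``.
    """
    return _simulate_run(config, concentration, seed)


def simulate_calibration_study(config: SimulationConfig) -> list[Electropherogram]:
    """Simulate ``levels × replicates`` runs with deterministic sub-seeds."""
    n_runs = len(config.calibration_levels) * config.replicates
    seeds = _subseeds(config.seed, n_runs)
    runs = []
    i = 0
    for li, conc in enumerate(config.calibration_levels):
        for rep in range(config.replicates):
            eg = _simulate_run(
                config, conc, int(seeds[i]), label=f"cal_L{li + 1}_R{rep + 1}"
            )
            eg.metadata["level_index"] = li
            eg.metadata["replicate_index"] = rep
            runs.append(eg)
            i += 1
    return runs


def simulate_sst_study(config: SimulationConfig, n: int = 10) -> list[Electropherogram]:
    """Simulate ``n`` system-suitability replicates at 100 µg/mL."""
    if n < 2:
        raise ValueError("SST needs at least 2 runs (SD undefined for n < 2)")
    seeds = _subseeds(config.seed + 1, n)
    return [
        _simulate_run(config, 100.0, int(seeds[i]), label=f"sst_{i + 1}") for i in range(n)
    ]


def simulate_degraded_sample(
    config: SimulationConfig, degraded_fraction: float, seed: int
) -> Electropherogram:
    """Simulate a stressed sample whose analyte peak is scaled by (1 − f).

    No interfering degradation-product peaks are synthesised; the degradation
    scenarios only shrink the analyte response.
    """
    if not (0.0 <= degraded_fraction < 1.0):
        raise ValueError(f"degraded_fraction must be in [0, 1), got {degraded_fraction}")
    return _simulate_run(
        config, 100.0, seed, area_scale=1.0 - degraded_fraction, label="degraded"
    )


def simulate_robustness_study(design, spec: RobustnessStudySpec):
    """Simulate per-run assay contents for a robustness design.

    Content of run ``r`` is ``base + Σ_j effects[j]·level(r, j) + noise``.
    Returns a DataFrame with columns ``run_id`` and ``content_percent``.
    """
    import pandas as pd

    levels = np.asarray(design.levels, dtype=float)
    effects = np.asarray(spec.factor_effects, dtype=float)
    if levels.shape[1] != effects.size:
        raise ValueError(
            f"factor_effects length {effects.size} does not match the "
            f"{levels.shape[1]}-factor design"
        )
    rng = np.random.default_rng(np.random.SeedSequence(int(spec.seed)))
    noise = rng.normal(0.0, spec.noise_sd, size=levels.shape[0])
    content = spec.base_content + levels @ effects + noise
    return pd.DataFrame(
        {"run_id": np.arange(1, levels.shape[0] + 1), "content_percent": content}
    )


def speciation_fractions(pkas: Sequence[float], ph_grid: Sequence[float]) -> SpeciesProfile:
    """Protonation-state distribution of a polyprotic analyte versus pH.

    Sequential macroscopic dissociation: with ``m`` pKa values there are
    ``m + 1`` states, and the population of the state that has lost ``k``
    protons at pH ``h`` is proportional to ``10^(Σ_{i≤k} (h − pKa_i))``,
    normalised within each pH.  Computed in log space for stability.
    """
    pkas_arr = np.asarray(pkas, dtype=float)
    ph = np.asarray(ph_grid, dtype=float)
    if pkas_arr.ndim != 1 or pkas_arr.size == 0:
        raise ValueError("pkas must be a non-empty 1-D sequence")
    if np.any(np.diff(pkas_arr) <= 0):
        raise ValueError("pkas must be strictly ascending")
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH values must be finite")
    # log10 weight of state k at each pH: cumulative sum of (pH − pKa_i)
    diffs = ph[:, None] - pkas_arr[None, :]  # (n_ph, m)
    logw = np.concatenate(
        [np.zeros((ph.size, 1)), np.cumsum(diffs, axis=1)], axis=1
    ) * _LN10  # natural log, (n_ph, m+1)
    logz = logsumexp(logw, axis=1, keepdims=True)
    fractions = np.exp(logw - logz)
    return SpeciesProfile(pkas=pkas_arr, ph_grid=ph, fractions=fractions)
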