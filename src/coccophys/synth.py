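"""Seeded synthetic-data generators.

Each generator emits data with the statistical structure its pipeline
stage assumes — exponential batch growth with multiplicative count
noise, lognormal morphometrics, SNARF traces of mixed responsive and
non-responsive subpopulations, voltage-clamp families of leak plus a
slowly activating outward conductance, and qPCR plates with configured
fold changes — together with the ground truth used to generate it, so
every stage can be tested round-trip with no external data.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import CellRecording, VoltageProtocol
from .physiology import CellMorphometry, CountSeries
from .snarf import Calibration, Phase, SNARFTrace, ph_to_ratio

__all__ = [
    "CultureConfig",
    "MorphometryConfig",
    "SnarfConfig",
    "EphysConfig",
    "QPCRConfig",
    "gen_culture",
    "gen_morphometrics",
    "gen_snarf_traces",
    "gen_current_family",
    "gen_tail_family",
    "gen_qpcr",
    "predicted_density_at",
]


# ---------------------------------------------------------------- cultures

@dataclass(frozen=True)
class CultureConfig:
    """Dilute batch growth: daily counts between ~500 and 4000 cells/mL."""

    mu: float = 0.55  # 1/day, within the species' 0.45-0.6 range
    n0: float = 500.0  # cells/mL at inoculation
    days: int = 3
    dt: float = 1.0  # days between counts
    count_cv: float = 0.05  # lognormal multiplicative noise
    n_replicates: int = 3


def gen_culture(config: CultureConfig, seed: int) -> list[CountSeries]:
    """Exponential trajectories with multiplicative lognormal count noise."""
    if config.mu < 0:
        raise ValueError("growth rate must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(config.days + 1) * config.dt
    out = []
    for r in range(config.n_replicates):
        clean = config.n0 * np.exp(config.mu * times)
        if config.count_cv > 0:
            sigma = math.sqrt(math.log(1.0 + config.count_cv ** 2))
            noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=times.size)
        else:
            noise = np.ones_like(times)
        out.append(
            CountSeries(
                times=tuple(times),
                densities=tuple(clean * noise),
                replicate_id=f"rep{r + 1}",
            )
        )
    return out


# ----------------------------------------------------------- morphometrics

@dataclass(frozen=True)
class MorphometryConfig:
    """Lognormal cell and coccolith size distributions.

    Defaults give a ~16-um decalcified cell (area ~200 um^2, POC ~300 pg)
    and ~8-um coccoliths, ~48 per cell including discarded ones, so the
    PIC/POC production ratio sits near 1.6: the heavily calcified
    C. braarudii phenotype at its pH optimum.
    """

    median_area: float = 200.0  # um^2
    area_cv: float = 0.15
    median_length: float = 8.0  # um
    length_cv: float = 0.08
    mean_coccolith_count: float = 48.0
    n_cells: int = 30


def gen_morphometrics(config: MorphometryConfig, seed: int) -> list[CellMorphometry]:
    if min(config.median_area, config.median_length, config.mean_coccolith_count) <= 0:
        raise ValueError("size parameters must be positive")
    rng = np.random.default_rng(seed)

    def lognorm(median: float, cv: float, size: int) -> np.ndarray:
        if cv == 0:
            return np.full(size, median)
        sigma = math.sqrt(math.log(1.0 + cv ** 2))
        return rng.lognormal(math.log(median), sigma, size=size)

    areas = lognorm(config.median_area, config.area_cv, config.n_cells)
    lengths = lognorm(config.median_length, config.length_cv, config.n_cells)
    counts = np.maximum(1, rng.poisson(config.mean_coccolith_count, config.n_cells))
    return [
        CellMorphometry(
            decalcified_area=float(a),
            coccolith_length=float(length),
            coccolith_count=int(n),
            cell_id=f"cell{i + 1}",
        )
        for i, (a, length, n) in enumerate(zip(areas, lengths, counts))
    ]


# ------------------------------------------------------------ SNARF traces

DEFAULT_SCHEDULE = (
    Phase(8.15, 0.0, 300.0),
    Phase(6.5, 300.0, 600.0),
    Phase(8.15, 600.0, 900.0),
)


@dataclass(frozen=True)
class SnarfConfig:
    """Mixed responsive / efflux-defective subpopulations.

    Responsive cells track external pH excursions with gain `gain` and a
    first-order relaxation; defective cells barely respond.  Fluorescence
    is generated by inverting the calibration with multiplicative noise.
    """

    n_cells: int = 100
    f_defective: float = 0.0
    baseline_ph: float = 6.85
    gain: float = 0.30  # d pH_cyt / d pH_o for responsive cells
    defective_gain: float = 0.01
    tau: float = 5.0  # s, relaxation time constant
    sample_dt: float = 0.3  # s (3.3 frames/s)
    fluor_cv: float = 0.01
    drift: float = 0.0  # imposed fractional terminal pH offset
    schedule: tuple[Phase, ...] = DEFAULT_SCHEDULE
    reference_pH: float = 8.15


def gen_snarf_traces(
    config: SnarfConfig, seed: int, cal: Calibration = Calibration()
) -> tuple[list[SNARFTrace], list[str]]:
    """Returns (traces, ground-truth labels 'responsive'/'defective')."""
    if not (0.0 <= config.f_defective <= 1.0):
        raise ValueError("f_defective must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_def = int(round(config.f_defective * config.n_cells))
    labels = ["defective"] * n_def + ["responsive"] * (config.n_cells - n_def)
    rng.shuffle(labels)

    t_end = max(p.end for p in config.schedule)
    times = np.arange(config.sample_dt, t_end, config.sample_dt)
    traces = []
    for i, label in enumerate(labels):
        gain = config.defective_gain if label == "defective" else config.gain
        ph = np.empty_like(times)
        current = config.baseline_ph
        prev_t = 0.0
        for j, t in enumerate(times):
            phase = next(p for p in config.schedule if p.start <= t < p.end)
            target = config.baseline_ph + gain * (phase.pH_o - config.reference_pH)
            current = target + (current - target) * math.exp(
                -(t - prev_t) / config.tau
            )
            ph[j] = current
            prev_t = t
        if config.drift != 0.0:
            # ramp starting after the first reference phase, so the imposed
            # offset between the flanking reference windows equals `drift`
            t0 = config.schedule[0].end
            ramp = np.clip((times - t0) / (t_end - t0), 0.0, 1.0)
            ph = ph + config.baseline_ph * config.drift * ramp
        ratio = ph_to_ratio(ph, cal)
        f580 = 1000.0 * np.exp(
            rng.normal(0.0, config.fluor_cv, size=times.size)
        )
        f630 = ratio * f580 * np.exp(
            rng.normal(0.0, config.fluor_cv, size=times.size)
        )
        traces.append(
            SNARFTrace(
                cell_id=f"cell{i + 1}",
                times=times,
                F580=f580,
                F630=f630,
                phase_schedule=config.schedule,
            )
        )
    return traces, labels


# ------------------------------------------------------- current families

@dataclass(frozen=True)
class EphysConfig:
    """Leak + slowly activating outward conductance (+ optional inward).

    The outward conductance opens with a Boltzmann above the configured
    reversal potential (the Hv phenotype: activation tracking E_H) and a
    first-order activation time constant.
    """

    protocol: VoltageProtocol = field(default_factory=VoltageProtocol)
    sample_interval: float = 1.0  # ms
    Cm: float = 40.0  # pF
    R_seal: float = 1.0  # GOhm
    g_out: float = 2.0  # nS, outward conductance amplitude
    E_rev: float = -70.0  # mV
    v_half_offset: float = 20.0  # mV above E_rev
    slope_factor: float = 8.0  # mV
    tau_act: float = 100.0  # ms
    inward_amp: float = 0.0  # pA, early Cl--like transient
    tau_inward: float = 20.0  # ms
    E_inward: float = -30.0  # mV
    noise_sd: float = 0.0  # pA additive Gaussian


def _activation(config: EphysConfig, v: np.ndarray, t: np.ndarray) -> np.ndarray:
    p_inf = 1.0 / (
        1.0 + np.exp(-(v - (config.E_rev + config.v_half_offset)) / config.slope_factor)
    )
    gate = 1.0 - np.exp(-t[:, None] / config.tau_act)
    return gate * p_inf[None, :]


def gen_current_family(config: EphysConfig, seed: int) -> CellRecording:
    """Synthetic sweep family; ground truth lives in the config itself."""
    rng = np.random.default_rng(seed)
    proto = config.protocol
    n_t = int(round(proto.step_duration / config.sample_interval))
    t = np.arange(n_t) * config.sample_interval
    v = np.asarray(proto.step_levels)

    leak = (v - proto.holding)[None, :] / config.R_seal  # pA
    outward = config.g_out * _activation(config, v, t) * (v - config.E_rev)[None, :]
    sweeps = leak + outward
    if config.inward_amp > 0:
        p_in = 1.0 / (1.0 + np.exp(-(v + 20.0) / 10.0))
        sweeps = sweeps - (
            config.inward_amp
            * p_in[None, :]
            * np.exp(-t[:, None] / config.tau_inward)
            * np.sign(np.maximum(v - config.E_inward, 0.0))[None, :]
        )
    if config.noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, config.noise_sd, size=sweeps.shape)
    return CellRecording(
        protocol=proto,
        sweeps=sweeps,
        sample_interval=config.sample_interval,
        Cm=config.Cm,
        R_seal=config.R_seal,
    )


def predicted_density_at(
    config: EphysConfig, voltage: float = 45.0, window_start: float = 500.0
) -> float:
    """Ground-truth pA/pF the classifier should see at `voltage`.

    Mirrors the analysis path: model steady currents at the two top
    protocol steps, linearly extrapolated to `voltage` — the generator's
    own arithmetic for the classification flip point.
    """
    proto = config.protocol
    t_end = np.array([proto.step_duration - config.sample_interval])
    v = np.asarray(proto.step_levels[-2:])
    i = (config.g_out * _activation(config, v, t_end) * (v - config.E_rev))[0]
    slope = (i[1] - i[0]) / (v[1] - v[0])
    return float((i[1] + slope * (voltage - v[1])) / config.Cm)


def gen_tail_family(
    config: EphysConfig,
    tail_levels: tuple[float, ...] = tuple(float(v) for v in range(-100, 1, 10)),
    prepulse: float = 40.0,
    tail_duration: float = 100.0,
    tau_deact: float = 15.0,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, ...], float]:
    """Leak-free tail-current segment after a fully activating prepulse.

    Returns (sweeps [time x tail level], tail levels, sample interval's
    start time of the tail = 0); currents decay from the instantaneous
    value g_out * (V_tail - E_rev).
    """
    rng = np.random.default_rng(seed)
    n_t = int(round(tail_duration / config.sample_interval))
    t = np.arange(n_t) * config.sample_interval
    v = np.asarray(tail_levels)
    p0 = 1.0 / (
        1.0
        + math.exp(
            -(prepulse - (config.E_rev + config.v_half_offset)) / config.slope_factor
        )
    )
    inst = config.g_out * p0 * (v - config.E_rev)
    sweeps = inst[None, :] * np.exp(-t[:, None] / tau_deact)
    if config.noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, config.noise_sd, size=sweeps.shape)
    return sweeps, tuple(float(x) for x in v), 0.0


# ------------------------------------------------------------------- qPCR

@dataclass(frozen=True)
class QPCRConfig:
    """Ct values consistent with configured fold changes.

    fold_changes maps (sample_id, target gene) -> expression relative to
    the calibrator sample; reference genes are generated constant across
    samples (perfect normalizers) before noise.
    """

    samples: tuple[str, ...] = ("pH7.55", "pH8.15", "pH8.75")
    calibrator: str = "pH8.15"
    targets: tuple[str, ...] = ("HV1", "HV2")
    references: tuple[str, ...] = ("EFL", "RPS1")
    fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    efficiency: float = 2.0
    base_ct_target: float = 24.0
    base_ct_reference: float = 20.0
    ct_noise_sd: float = 0.0
    tech_replicates: int = 3


def gen_qpcr(config: QPCRConfig, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    if any(f <= 0 for f in config.fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rows = []
    for sample in config.samples:
        for gene in config.targets + config.references:
            if gene in config.targets:
                fold = config.fold_changes.get((sample, gene), 1.0)
                # fold-change f => Ct lower by log_E(f) relative to calibrator
                ct = config.base_ct_target - math.log(fold, config.efficiency)
                role = "target"
            else:
                ct = config.base_ct_reference
                role = "reference"
            for rep in range(config.tech_replicates):
                noisy = ct + (
                    rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                )
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "role": role,
                        "Ct": noisy,
                        "efficiency": config.efficiency,
                        "technical_replicate": rep + 1,
                    }
                )
    return pd.DataFrame(rows)
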