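"""Synthetic greenhouse data with the statistical structure of a real drought trial.

One latent per-plant state trajectory (biomass, height, hydration, chlorosis,
turgor, xylem-sap ion concentration) drives every modality — the implanted
biosensor trace, the multi-view plant images and the manual physiology tables —
so that cross-modal correlations (sensor response vs stomatal conductance,
sensor response vs biovolume) are emergent rather than imposed.

Default effect sizes are the ones reported for the tomato trials the pipeline
targets: stress onset detectable ~30 h after water withholding, a 15% height
deficit by stress day 6, stomatal conductance reduced ~4.5-fold during stress
days 7-14, relative water content reduced ~23% at peak stress, SPAD elevated
under stress, and a post-rewatering sensor-response plateau well below the
pre-stress baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTROL, STRESSED, ExperimentDesign, build_design

__all__ = [
    "GeneratorConfig",
    "PlantStateTrajectory",
    "simulate_latent_states",
    "synthesize_sensor_trace",
    "synthesize_all_traces",
    "sample_physiology",
    "ion_response",
    "ion_from_response_fraction",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    All rates are per day unless noted; setting ``seed`` fixes every random
    draw, so identical configs produce bit-identical outputs.
    """

    seed: int = 0
    n_per_group: int = 4
    sampling_interval_min: int = 15

    # sensor
    r_baseline: float = -0.5          # sensor response R at reference sap conc
    diurnal_amplitude: float = 0.15   # fractional day-time deepening of R
    onset_lag_h: float = 30.0         # hours from water withholding to sap change
    pii_decline_rate: float = 0.12    # NR units/day during drought decline
    da_start_day: float = 4.5         # absolute day DA rebound begins
    da_duration_d: float = 2.5
    da_rebound_fraction: float = 0.5  # fraction of preceding decline recovered
    recovery_fraction: float = 0.7    # NR plateau after rewatering (of pre-stress)
    noise_sd_sensor: float = 0.01     # additive SD on per-sample R
    ion_ref_mol_l: float = 0.05       # sap ionic strength at full watering
    ion_c0_mol_l: float = 0.005       # saturation scale of the ion response

    # growth / morphology
    growth_rate: float = 0.12         # logistic biomass growth rate, 1/day
    biomass_capacity: float = 4.0
    height_deficit_frac: float = 0.15  # stressed/control height gap by stress day 6
    height0_px: float = 40.0
    height_growth_px: float = 3.0     # px/day
    height_max_px: float = 118.0

    # hydration / chlorosis / turgor
    rwc_drop_frac: float = 0.23
    hydration_dip_window: tuple[float, float] = (7.0, 10.0)  # absolute days
    hydration_dip_depth: float = 0.35
    hydration_bump: float = 0.10      # partial relief at the LIMITED day
    chlorosis_rate: float = 0.02      # fraction/day under stress
    chlorosis_rate_control: float = 0.006
    chlorosis_plateau: float = 0.25
    turgor_min: float = 0.55

    # physiology
    sc_fold_reduction: float = 4.5
    sc_control_mean: float = 350.0    # mmol m^-2 s^-1
    rwc_control: float = 0.92
    spad_control_mean: float = 42.0
    spad_stress_shift: float = 4.0
    noise_frac_physio: float = 0.04   # multiplicative SD on SC
    noise_sd_rwc: float = 0.015
    noise_sd_spad: float = 2.0
    plant_scale_sd: float = 0.03      # fixed per-plant device/size variation

    # imaging
    image_size: int = 160
    area_per_biomass_px: float = 750.0

    def __post_init__(self) -> None:
        for name in (
            "diurnal_amplitude", "pii_decline_rate", "noise_sd_sensor",
            "growth_rate", "height_deficit_frac", "rwc_drop_frac",
            "chlorosis_rate", "noise_frac_physio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.recovery_fraction < 1:
            raise ValueError("recovery_fraction must lie in (0, 1)")
        if self.sc_fold_reduction < 1:
            raise ValueError("sc_fold_reduction must be >= 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def null_effect(cls, **kw) -> "GeneratorConfig":
        """A config in which stress has no effect on any modality."""
        base = dict(
            pii_decline_rate=0.0,
            da_rebound_fraction=0.0,
            recovery_fraction=1.0 - 1e-9,
            height_deficit_frac=0.0,
            hydration_dip_depth=0.0,
            hydration_bump=0.0,
            chlorosis_rate=cls.chlorosis_rate_control,
            turgor_min=1.0,
            sc_fold_reduction=1.0,
            rwc_drop_frac=0.0,
            spad_stress_shift=0.0,
        )
        base.update(kw)
        return cls(**base)


@dataclass
class PlantStateTrajectory:
    """Daily latent state of one plant plus a sub-daily sap-ion trajectory."""

    plant_id: str
    group: str
    days: np.ndarray           # integer day index, 0..duration-1
    biomass: np.ndarray        # arbitrary units, monotone for controls
    height_px: np.ndarray
    hydration: np.ndarray      # [0, 1]
    chlorosis_frac: np.ndarray  # [0, 1]
    turgor: np.ndarray         # [0, 1]
    sap_ion_conc: np.ndarray   # mol/L, sampled at day midpoints
    conc_knots_h: np.ndarray   # piecewise-linear sap conc vs hours
    conc_knots: np.ndarray
    r_scale: float = 1.0       # fixed per-plant device gain

    def conc_at_hours(self, hours: np.ndarray) -> np.ndarray:
        return np.interp(hours, self.conc_knots_h, self.conc_knots)


# ---------------------------------------------------------------------------
# the saturating ion-response map g


def ion_response(conc: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Sensor response at sap ion concentration ``conc`` (mol/L).

    A saturating, monotone map: R(c) = r_baseline * log10(1 + c/c0) /
    log10(1 + c_ref/c0), so R equals ``r_baseline`` at the reference
    concentration and |R| increases with log-concentration.
    """
    c = np.asarray(conc, dtype=float)
    num = np.log10(1.0 + c / config.ion_c0_mol_l)
    den = np.log10(1.0 + config.ion_ref_mol_l / config.ion_c0_mol_l)
    return config.r_baseline * num / den


def ion_from_response_fraction(frac: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Inverse of :func:`ion_response` expressed as a fraction of baseline |R|."""
    f = np.asarray(frac, dtype=float)
    ratio = 1.0 + config.ion_ref_mol_l / config.ion_c0_mol_l
    return config.ion_c0_mol_l * (np.power(ratio, f) - 1.0)


# ---------------------------------------------------------------------------
# latent-state simulation


def _ramp(x: np.ndarray, x0: float, x1: float) -> np.ndarray:
    """Piecewise-linear 0->1 ramp between x0 and x1."""
    if x1 <= x0:
        return (np.asarray(x, dtype=float) >= x0).astype(float)
    return np.clip((np.asarray(x, dtype=float) - x0) / (x1 - x0), 0.0, 1.0)


def _nr_target_knots(
    config: GeneratorConfig, design: ExperimentDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Knots (hours, value) of the stressed group's target response fraction.

    The fraction multiplies the baseline response, so it is also the expected
    normalized response NR of a stressed/control group pair: flat at 1 until
    ``onset_lag_h`` after water withholding, linear decline during early
    drought, a partial drought-avoidance rebound, a second decline to a stable
    floor, and a partial rise after rewatering to ``recovery_fraction``.
    """
    s0 = design.stress_start_day
    end_h = design.duration_days * 24.0
    if s0 is None or config.pii_decline_rate == 0.0:
        return np.array([0.0, end_h]), np.array([1.0, 1.0])

    onset_h = s0 * 24.0 + config.onset_lag_h
    rate_h = config.pii_decline_rate / 24.0

    da_s = max(config.da_start_day * 24.0, onset_h)
    f1 = 1.0 - rate_h * (da_s - onset_h)
    da_e = da_s + config.da_duration_d * 24.0
    f2 = f1 + config.da_rebound_fraction * (1.0 - f1)

    rw = design.rewatering_day
    rw_h = rw * 24.0 if rw is not None else end_h
    # second decline to a floor midway through the drought, then flat
    trough_h = min(da_e + 2.5 * 24.0, rw_h)
    f3 = max(f2 - rate_h * (trough_h - da_e), 0.05)

    hours = [0.0, onset_h, da_s, da_e, trough_h]
    vals = [1.0, 1.0, f1, f2, f3]
    if rw is not None:
        rec_h = min(rw_h + 48.0, end_h)
        hours += [rw_h, rec_h, end_h]
        vals += [f3, config.recovery_fraction, config.recovery_fraction]
        # a second drought block (PIV) pulls the response down again, faster
        blocks = design.drought_blocks
        if len(blocks) > 1:
            s2_h = blocks[1][0] * 24.0
            f4 = max(config.recovery_fraction - 2.0 * rate_h * (end_h - s2_h - 24.0), 0.05)
            hours = [h for h, v in zip(hours, vals) if h <= s2_h] + [s2_h + 24.0, end_h]
            vals = vals[: len(hours) - 2] + [config.recovery_fraction, f4]
    else:
        hours.append(end_h)
        vals.append(f3)
    h = np.array(hours)
    v = np.array(vals)
    keep = np.concatenate([[True], np.diff(h) > 0])
    return h[keep], v[keep]


def simulate_latent_states(
    config: GeneratorConfig, design: ExperimentDesign
) -> list[PlantStateTrajectory]:
    """Simulate daily latent states for ``2 * n_per_group`` plants.

    Stressed plants slow their biomass growth from stress onset, reach a
    ``height_deficit_frac`` height gap by stress day 6 and keep it, lose turgor
    over stress days 4-14 with recovery after rewatering, show a hydration dip
    inside ``hydration_dip_window`` with a bump at the LIMITED irrigation day,
    accumulate chlorosis to a plateau, and follow the sap-ion trajectory
    implied by the target response-fraction profile. Controls grow smoothly
    with small noise and keep all bounded fields near their initial values.
    """
    rng = np.random.default_rng(config.seed)
    days = np.arange(design.duration_days)
    s0 = design.stress_start_day
    rw = design.rewatering_day
    knots_h, knots_f = _nr_target_knots(config, design)
    c_knots = ion_from_response_fraction(knots_f, config)

    out: list[PlantStateTrajectory] = []
    for group in (CONTROL, STRESSED):
        stressed = group == STRESSED and s0 is not None
        for i in range(config.n_per_group):
            plant_id = f"{group[0].upper()}{i + 1}"
            scale = float(1.0 + config.plant_scale_sd * rng.standard_normal())

            # biomass: logistic growth, slowed by stress severity
            sev = np.zeros_like(days, dtype=float)
            if stressed:
                sev = _ramp(days, s0, s0 + 6)
                if rw is not None:
                    sev = np.where(days >= rw, 0.4 * sev, sev)
            biomass = np.empty(len(days))
            b = 1.0 * scale
            for d in range(len(days)):
                biomass[d] = b
                g = config.growth_rate * (1.0 - 0.85 * sev[d])
                b = b * (1.0 + g * max(0.0, 1.0 - b / config.biomass_capacity))

            # height: saturating growth; stressed plants carry a visible
            # (wilting-inclusive) deficit ramping to height_deficit_frac by
            # stress day 6 and held thereafter
            h_pot = np.minimum(
                config.height0_px + config.height_growth_px * days,
                config.height_max_px,
            ) * scale
            deficit = (
                config.height_deficit_frac * _ramp(days, s0, s0 + 6)
                if stressed
                else np.zeros_like(days, dtype=float)
            )
            height = h_pot * (1.0 - deficit) * (
                1.0 + 0.01 * rng.standard_normal(len(days))
            )

            # turgor: falls over stress days 4-14, recovers after rewatering
            turgor = np.ones(len(days))
            if stressed and config.turgor_min < 1.0:
                drop = (1.0 - config.turgor_min) * _ramp(days, s0 + 4, s0 + 14)
                turgor = 1.0 - drop
                if rw is not None:
                    rec = _ramp(days, rw, rw + 3)
                    turgor = turgor + rec * (0.95 - turgor) * (days >= rw)
            turgor = np.clip(turgor + 0.01 * rng.standard_normal(len(days)), 0.0, 1.0)

            # hydration: dip inside the window, bump at LIMITED day, restored
            hydration = np.ones(len(days))
            if stressed and config.hydration_dip_depth > 0:
                lo, hi = config.hydration_dip_window
                dip = config.hydration_dip_depth * _ramp(days, lo, hi)
                hydration = 1.0 - dip
                for lday in design.limited_days:
                    bump = config.hydration_bump * np.exp(
                        -np.clip(days - lday - 1, 0, None) / 2.0
                    ) * (days > lday)
                    hydration = np.minimum(hydration + bump, 1.0)
                if rw is not None:
                    hydration = np.where(
                        days >= rw + 1, 1.0, hydration
                    )
            hydration = np.clip(
                hydration + 0.01 * rng.standard_normal(len(days)), 0.0, 1.0
            )

            # chlorosis: slow drift for controls, faster rise to a plateau
            # under stress that flattens once established
            base_chl = config.chlorosis_rate_control * days
            if stressed:
                stress_days = np.clip(days - (s0 + 2), 0, None)
                chl = base_chl + np.minimum(
                    config.chlorosis_rate * stress_days,
                    config.chlorosis_plateau,
                )
            else:
                chl = base_chl
            chlorosis = np.clip(chl + 0.005 * rng.standard_normal(len(days)), 0.0, 1.0)

            if stressed:
                ck_h, ck = knots_h, c_knots
            else:
                ck_h = np.array([0.0, design.duration_days * 24.0])
                ck = np.full(2, config.ion_ref_mol_l)
            sap = np.interp(days + 0.5, ck_h / 24.0, ck)

            out.append(
                PlantStateTrajectory(
                    plant_id=plant_id,
                    group=group,
                    days=days.copy(),
                    biomass=biomass,
                    height_px=height,
                    hydration=hydration,
                    chlorosis_frac=chlorosis,
                    turgor=turgor,
                    sap_ion_conc=sap,
                    conc_knots_h=ck_h.copy(),
                    conc_knots=ck.copy(),
                    r_scale=scale,
                )
            )
    return out


# ---------------------------------------------------------------------------
# sensor trace synthesis


def diurnal_factor(
    hours: np.ndarray, photoperiod_h: float, amplitude: float
) -> np.ndarray:
    """Multiplicative diurnal term: a half-sine during the photoperiod, 0 at night.

    The factor deepens a negative baseline response during daytime, matching
    sensors whose response falls in the day and rises at night.
    """
    tod = np.asarray(hours, dtype=float) % 24.0
    day = tod < photoperiod_h
    return np.where(day, amplitude * np.sin(np.pi * tod / photoperiod_h), 0.0)


def synthesize_sensor_trace(
    state: PlantStateTrajectory,
    config: GeneratorConfig,
    design: ExperimentDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthesize a raw drain-current trace for one plant.

    The trace encodes R(t) = g(sap_conc(t)) * scale * (1 + diurnal) + noise via
    ``i_ds = i_ds0 * (1 + R)`` on a slowly drifting negative gate-off baseline.
    Columns: plant_id, group, time_min, i_ds_uA, i_ds0_uA.
    """
    if (24 * 60) % config.sampling_interval_min != 0:
        raise ValueError("sampling_interval_min must divide 24 h")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_min = np.arange(0, design.duration_days * 1440, config.sampling_interval_min)
    hours = t_min / 60.0

    conc = state.conc_at_hours(hours)
    r = ion_response(conc, config) * state.r_scale
    r = r * (1.0 + diurnal_factor(hours, design.photoperiod_h, config.diurnal_amplitude))
    r = r + config.noise_sd_sensor * rng.standard_normal(len(t_min))

    # gate-off baseline: slow exponential drift plus small measurement noise
    i0 = -40.0 * (1.0 + 0.04 * (1.0 - np.exp(-hours / 200.0)))
    i0 = i0 * (1.0 + 0.001 * rng.standard_normal(len(t_min)))
    i_ds = i0 * (1.0 + r)

    return pd.DataFrame(
        {
            "plant_id": state.plant_id,
            "group": state.group,
            "time_min": t_min.astype(int),
            "i_ds_uA": i_ds,
            "i_ds0_uA": i0,
        }
    )


def synthesize_all_traces(
    states: list[PlantStateTrajectory],
    config: GeneratorConfig,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Traces for all plants, concatenated, with one stream of randomness."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    return pd.concat(
        [synthesize_sensor_trace(s, config, design, rng) for s in states],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# physiology sampling


def _sc_fold(day: float, config: GeneratorConfig, design: ExperimentDesign) -> float:
    """Fold reduction of stomatal conductance on an absolute day."""
    s0 = design.stress_start_day
    if s0 is None or config.sc_fold_reduction <= 1.0:
        return 1.0
    sd = day - s0  # stress day
    rw = design.rewatering_day
    if rw is not None and day >= rw:
        # near-complete recovery within three days of rewatering
        rec = min((day - rw) / 3.0, 1.0)
        return config.sc_fold_reduction * (1.0 - rec) + 1.2 * rec if rec < 1 else 1.2
    if sd < 2:
        return 1.0
    if sd < 7:
        return 1.0 + (config.sc_fold_reduction - 1.0) * (sd - 2) / 5.0
    return config.sc_fold_reduction


def _rwc_true(day: float, config: GeneratorConfig, design: ExperimentDesign) -> float:
    s0 = design.stress_start_day
    base = config.rwc_control
    if s0 is None or config.rwc_drop_frac <= 0:
        return base
    rw = design.rewatering_day
    if rw is not None and day >= rw + 2:
        return base  # completely restored after rewatering
    ramp = min(max((day - s0 - 4) / 6.0, 0.0), 1.0)
    return base * (1.0 - config.rwc_drop_frac * ramp)


def sample_physiology(
    states: list[PlantStateTrajectory],
    config: GeneratorConfig,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Sample the manual physiology table on the design's physiology days.

    Per plant and day: stomatal conductance from 2 leaves (SC), one
    fresh/turgid/dry weight triplet per replicate for RWC (FW, TW, DW; 2
    replicates), and 10 SPAD leaf readings. Long format with columns
    plant_id, group, day, measure, replicate, value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    rows: list[tuple] = []
    for day in design.physio_days:
        fold = _sc_fold(day, config, design)
        rwc_s = _rwc_true(day, config, design)
        for st in states:
            stressed = st.group == STRESSED
            sc_true = config.sc_control_mean * st.r_scale
            if stressed:
                sc_true = sc_true / fold
            for rep in range(1, 3):
                v = sc_true * (1.0 + config.noise_frac_physio * rng.standard_normal())
                rows.append((st.plant_id, st.group, day, "SC", rep, max(v, 1.0)))

            rwc = rwc_s if stressed else config.rwc_control
            for rep in range(1, 3):
                rv = np.clip(rwc + config.noise_sd_rwc * rng.standard_normal(), 0.0, 1.0)
                dw = 0.50 * (1.0 + 0.05 * rng.standard_normal())
                tw = dw + 4.1 * (1.0 + 0.05 * rng.standard_normal())
                fw = dw + rv * (tw - dw)
                rows.append((st.plant_id, st.group, day, "FW", rep, fw))
                rows.append((st.plant_id, st.group, day, "TW", rep, tw))
                rows.append((st.plant_id, st.group, day, "DW", rep, dw))

            spad = config.spad_control_mean
            if stressed and design.stress_start_day is not None:
                s0 = design.stress_start_day
                rw = design.rewatering_day
                in_stress = day >= s0 + 2 and (rw is None or day < rw + 2)
                if in_stress:
                    spad = spad + config.spad_stress_shift
            for rep in range(1, 11):
                v = spad + config.noise_sd_spad * rng.standard_normal()
                rows.append((st.plant_id, st.group, day, "SPAD", rep, max(v, 0.0)))

    return pd.DataFrame(
        rows, columns=["plant_id", "group", "day", "measure", "replicate", "value"]
    )
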