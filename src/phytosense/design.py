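"""Experiment designs for drought-stress trials.

A design encodes, on a common day grid, the watering schedule of each plant
group, the imaging and physiology sampling days, and the photoperiod. Day 0
is the day of biosensor implantation; all timestamps elsewhere in the package
are minutes since implantation. The two built-in presets reproduce the two
greenhouse trials the pipeline was developed around:

* ``PILOT`` — 16 h photoperiod; 3 d settling after implantation (SI), 14 d of
  withheld watering (DSI), 2 d of rewatering (RE) and a second 6 d drought
  episode (DSII); 25 d total.
* ``MAIN`` — 12 h photoperiod; 1 d settling, 16 d of withheld watering with a
  single 50 cm^3 emergency irrigation on day 8, then 7 d of rewatering;
  24 d total, imaging every other day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "Watering",
    "WateringState",
    "ExperimentDesign",
    "PlantRecord",
    "PhaseWindow",
    "DesignError",
    "build_design",
    "phase_label_template",
    "design_to_yaml",
    "design_from_yaml",
]

CONTROL = "control"
STRESSED = "stressed"


class DesignError(ValueError):
    """Raised when a design violates its invariants."""


class Watering(str, enum.Enum):
    FULL = "FULL"
    WITHHELD = "WITHHELD"
    LIMITED = "LIMITED"
    REWATERED = "REWATERED"


@dataclass(frozen=True)
class WateringState:
    """Watering condition of one group on one day.

    ``limited_volume_cm3`` is required exactly when the state is LIMITED and
    must be positive (the emergency irrigation supplied to keep a wilting
    plant imageable).
    """

    state: Watering
    limited_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.state is Watering.LIMITED:
            if self.limited_volume_cm3 is None or self.limited_volume_cm3 <= 0:
                raise DesignError("LIMITED watering requires a positive volume")
        elif self.limited_volume_cm3 is not None:
            raise DesignError("limited_volume_cm3 only valid for LIMITED state")


@dataclass(frozen=True)
class PlantRecord:
    plant_id: str
    cultivar: str
    group: str  # CONTROL or STRESSED


@dataclass(frozen=True)
class PhaseWindow:
    """One expected phase of the normalized sensor response trajectory.

    ``start_day``/``end_day`` are half-open day bounds; for the drought
    avoidance phase (DA) they are None because its bounds are only determined
    by change-point segmentation of the measured series, not by the schedule.
    """

    label: str  # PI, PII, DA, PIII, PIV
    start_day: int | None
    end_day: int | None
    parent: str | None = None  # DA is a sub-window of PII


@dataclass
class ExperimentDesign:
    duration_days: int
    photoperiod_h: float
    sampling_interval_min: int
    schedule: dict[str, list[WateringState]]
    imaging_days: tuple[int, ...] = ()
    physio_days: tuple[int, ...] = ()
    name: str = "custom"

    def __post_init__(self) -> None:
        self.imaging_days = tuple(sorted(self.imaging_days))
        self.physio_days = tuple(sorted(self.physio_days))
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.duration_days <= 0:
            raise DesignError("duration_days must be positive")
        if not 0 < self.photoperiod_h < 24:
            raise DesignError("photoperiod_h must lie in (0, 24)")
        if self.sampling_interval_min <= 0:
            raise DesignError("sampling_interval_min must be positive")
        if set(self.schedule) != {CONTROL, STRESSED}:
            raise DesignError("schedule must define 'control' and 'stressed' groups")
        for group, states in self.schedule.items():
            if len(states) != self.duration_days:
                raise DesignError(
                    f"schedule for {group!r} has {len(states)} days, "
                    f"expected {self.duration_days}"
                )
        if any(s.state is Watering.WITHHELD for s in self.schedule[CONTROL]):
            raise DesignError("control group must never have watering withheld")
        for day in self.imaging_days:
            if not 0 <= day < self.duration_days:
                raise DesignError(f"imaging day {day} outside [0, {self.duration_days})")
        for day in self.physio_days:
            if not 0 <= day < self.duration_days:
                raise DesignError(f"physio day {day} outside [0, {self.duration_days})")

    # -- derived schedule landmarks ----------------------------------------
    @property
    def stressed_states(self) -> list[WateringState]:
        return self.schedule[STRESSED]

    def _days_in(self, *states: Watering) -> list[int]:
        return [d for d, s in enumerate(self.stressed_states) if s.state in states]

    @property
    def stress_start_day(self) -> int | None:
        """First WITHHELD day of the stressed group, None if never stressed."""
        days = self._days_in(Watering.WITHHELD)
        return days[0] if days else None

    @property
    def rewatering_day(self) -> int | None:
        days = self._days_in(Watering.REWATERED)
        return days[0] if days else None

    @property
    def limited_days(self) -> tuple[int, ...]:
        return tuple(self._days_in(Watering.LIMITED))

    @property
    def drought_blocks(self) -> list[tuple[int, int]]:
        """Contiguous half-open [start, end) blocks of drought.

        A LIMITED day inside a WITHHELD run is part of the same drought block:
        the emergency irrigation interrupts watering-withheld bookkeeping, not
        the stress episode.
        """
        days = sorted(self._days_in(Watering.WITHHELD, Watering.LIMITED))
        # a LIMITED day only counts when adjacent to a WITHHELD day
        withheld = set(self._days_in(Watering.WITHHELD))
        blocks: list[tuple[int, int]] = []
        for d in days:
            if blocks and d == blocks[-1][1]:
                blocks[-1] = (blocks[-1][0], d + 1)
            else:
                blocks.append((d, d + 1))
        return [b for b in blocks if any(d in withheld for d in range(b[0], b[1]))]

    @property
    def stress_start_min(self) -> float | None:
        d = self.stress_start_day
        return None if d is None else d * 1440.0


# ---------------------------------------------------------------------------
# presets


def _run(state: Watering, n: int, volume: float | None = None) -> list[WateringState]:
    return [WateringState(state, volume) for _ in range(n)]


def build_design(
    preset: str | None = None,
    **fields,
) -> ExperimentDesign:
    """Build an :class:`ExperimentDesign` from a preset or explicit fields.

    Parameters
    ----------
    preset:
        ``"PILOT"`` or ``"MAIN"`` (case-insensitive), or None to build from
        explicit keyword fields (``duration_days``, ``photoperiod_h``,
        ``sampling_interval_min``, ``schedule``, ...).
    fields:
        Overrides applied on top of the preset, e.g. ``limited_day=10`` to
        move the MAIN preset's emergency-irrigation day.
    """
    if preset is None:
        return ExperimentDesign(**fields)

    preset = preset.upper()
    if preset == "PILOT":
        # SI days 0-2, DSI days 3-16 (14 d), RE days 17-18, DSII days 19-24
        stressed = (
            _run(Watering.FULL, 3)
            + _run(Watering.WITHHELD, 14)
            + _run(Watering.REWATERED, 2)
            + _run(Watering.WITHHELD, 6)
        )
        base = dict(
            duration_days=25,
            photoperiod_h=16.0,
            sampling_interval_min=15,
            schedule={CONTROL: _run(Watering.FULL, 25), STRESSED: stressed},
            imaging_days=(),
            physio_days=(7, 14),
            name="PILOT",
        )
    elif preset == "MAIN":
        limited_day = int(fields.pop("limited_day", 8))
        # SI day 0, DSI days 1-16 (16 d) with one LIMITED day, RE days 17-23
        stressed = (
            _run(Watering.FULL, 1)
            + _run(Watering.WITHHELD, 16)
            + _run(Watering.REWATERED, 7)
        )
        if not 1 <= limited_day <= 16:
            raise DesignError("limited_day must fall inside the drought window")
        stressed[limited_day] = WateringState(Watering.LIMITED, 50.0)
        base = dict(
            duration_days=24,
            photoperiod_h=12.0,
            sampling_interval_min=15,
            schedule={CONTROL: _run(Watering.FULL, 24), STRESSED: stressed},
            imaging_days=tuple(range(0, 24, 2)),
            physio_days=(0, 7, 14, 21),
            name="MAIN",
        )
    else:
        raise DesignError(f"unknown preset {preset!r}")

    base.update(fields)
    return ExperimentDesign(**base)


# ---------------------------------------------------------------------------
# phase template


def phase_label_template(design: ExperimentDesign) -> list[PhaseWindow]:
    """Expected phase windows for a design.

    PI runs from implantation to the first drought day; PII spans the first
    drought block; DA is a sub-window of PII with bounds left to change-point
    segmentation; PIII starts at rewatering; PIV is present only when a second
    drought block exists. Windows tile ``[0, duration_days)`` (DA excepted).
    """
    blocks = design.drought_blocks
    if not blocks:
        return [PhaseWindow("PI", 0, design.duration_days)]

    first = blocks[0]
    windows = [
        PhaseWindow("PI", 0, first[0]),
        PhaseWindow("PII", first[0], first[1]),
        PhaseWindow("DA", None, None, parent="PII"),
    ]
    if len(blocks) > 1:
        second = blocks[1]
        windows.append(PhaseWindow("PIII", first[1], second[0]))
        windows.append(PhaseWindow("PIV", second[0], design.duration_days))
    else:
        windows.append(PhaseWindow("PIII", first[1], design.duration_days))
    return windows


# ---------------------------------------------------------------------------
# serialization


def _schedule_to_blocks(states: list[WateringState]) -> list[dict]:
    blocks: list[dict] = []
    for day, ws in enumerate(states):
        if (
            blocks
            and blocks[-1]["state"] == ws.state.value
            and blocks[-1].get("volume_cm3") == ws.limited_volume_cm3
            and blocks[-1]["end_day"] == day
        ):
            blocks[-1]["end_day"] = day + 1
        else:
            blk = {"state": ws.state.value, "start_day": day, "end_day": day + 1}
            if ws.limited_volume_cm3 is not None:
                blk["volume_cm3"] = ws.limited_volume_cm3
            blocks.append(blk)
    return blocks


def _schedule_from_blocks(blocks: list[dict], duration: int) -> list[WateringState]:
    states: list[WateringState | None] = [None] * duration
    for blk in blocks:
        for day in range(int(blk["start_day"]), int(blk["end_day"])):
            if not 0 <= day < duration:
                raise DesignError(f"schedule block day {day} outside design")
            if states[day] is not None:
                raise DesignError(f"overlapping schedule blocks at day {day}")
            states[day] = WateringState(Watering(blk["state"]), blk.get("volume_cm3"))
    missing = [d for d, s in enumerate(states) if s is None]
    if missing:
        raise DesignError(f"schedule has gaps at days {missing}")
    return states  # type: ignore[return-value]


def design_to_yaml(design: ExperimentDesign, path=None) -> str:
    doc = {
        "name": design.name,
        "duration_days": design.duration_days,
        "photoperiod_h": design.photoperiod_h,
        "sampling_interval_min": design.sampling_interval_min,
        "groups": [
            {"name": g, "schedule": _schedule_to_blocks(design.schedule[g])}
            for g in (CONTROL, STRESSED)
        ],
        "imaging_days": list(design.imaging_days),
        "physio_days": list(design.physio_days),
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def design_from_yaml(source) -> ExperimentDesign:
    """Read a design from a YAML string or file path."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and not text.strip().startswith("{"):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    duration = int(doc["duration_days"])
    schedule = {
        g["name"]: _schedule_from_blocks(g["schedule"], duration)
        for g in doc["groups"]
    }
    return ExperimentDesign(
        duration_days=duration,
        photoperiod_h=float(doc["photoperiod_h"]),
        sampling_interval_min=int(doc["sampling_interval_min"]),
        schedule=schedule,
        imaging_days=tuple(doc.get("imaging_days", ())),
        physio_days=tuple(doc.get("physio_days", ())),
        name=doc.get("name", "custom"),
    )
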