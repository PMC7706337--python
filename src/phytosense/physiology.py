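"""Manual physiological measures: relative water content, relative SPAD and
stomatal-conductance fold change.

Relative water content follows the classic fresh/turgid/dry weight formula
RWC = 100 * (FW - DW) / (TW - DW). Relative SPAD is a plant's mean SPAD
reading divided by the same-day control-group mean (a baseline-day
normalization is available via ``reference="day0"``). The stomatal
conductance fold change is the control-group mean over the stressed-group
mean on a given day.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import CONTROL, STRESSED, ExperimentDesign

__all__ = [
    "compute_rwc",
    "relative_spad",
    "sc_fold_change",
    "physio_summary",
]


def compute_rwc(fw: float, tw: float, dw: float) -> float:
    """Relative water content in percent: 100 * (fw - dw) / (tw - dw).

    Raises when tw <= dw; a fresh weight outside [dw, tw] is flagged as a
    probable measurement error (warning) but the value is still returned.
    """
    fw, tw, dw = float(fw), float(tw), float(dw)
    if tw <= dw:
        raise ValueError("turgid weight must exceed dry weight")
    if not dw <= fw <= tw:
        warnings.warn(
            f"fresh weight {fw} outside [dry={dw}, turgid={tw}]; "
            "probable measurement error",
            stacklevel=2,
        )
    return 100.0 * (fw - dw) / (tw - dw)


def relative_spad(plant_mean: float, control_mean: float) -> float:
    """Plant mean SPAD divided by the same-day control-group mean."""
    if not control_mean > 0:
        raise ValueError("control mean SPAD must be positive")
    return float(plant_mean) / float(control_mean)


def sc_fold_change(control_mean: float, stressed_mean: float) -> float:
    """Control-group over stressed-group mean stomatal conductance."""
    if stressed_mean == 0:
        raise ValueError("stressed mean conductance is zero")
    return float(control_mean) / float(stressed_mean)


def _rwc_per_plant(physio: pd.DataFrame) -> pd.DataFrame:
    """Per plant/day/replicate RWC from the FW/TW/DW triplets."""
    w = physio[physio["measure"].isin(["FW", "TW", "DW"])]
    if w.empty:
        return pd.DataFrame(columns=["plant_id", "group", "day", "rwc_pct"])
    wide = w.pivot_table(
        index=["plant_id", "group", "day", "replicate"],
        columns="measure",
        values="value",
    ).reset_index()
    wide["rwc_pct"] = [
        compute_rwc(fw, tw, dw)
        for fw, tw, dw in zip(wide["FW"], wide["TW"], wide["DW"])
    ]
    return (
        wide.groupby(["plant_id", "group", "day"])["rwc_pct"].mean().reset_index()
    )


def physio_summary(
    physio: pd.DataFrame,
    design: ExperimentDesign | None = None,
    spad_reference: str = "control",
) -> pd.DataFrame:
    """Group-level summary per day: SC means and fold change, RWC%, relative SPAD.

    ``spad_reference`` chooses the relative-SPAD denominator: the same-day
    control-group mean (default) or each group's own day-0 mean (``"day0"``).
    """
    if spad_reference not in ("control", "day0"):
        raise ValueError("spad_reference must be 'control' or 'day0'")
    rows = []
    rwc = _rwc_per_plant(physio)
    sc = physio[physio["measure"] == "SC"]
    spad = physio[physio["measure"] == "SPAD"]
    for day in sorted(physio["day"].unique()):
        row: dict = {"day": day}
        sc_d = sc[sc["day"] == day]
        means = sc_d.groupby("group")["value"].mean()
        if CONTROL in means.index:
            row["sc_control"] = means[CONTROL]
        if STRESSED in means.index:
            row["sc_stressed"] = means[STRESSED]
        if CONTROL in means.index and STRESSED in means.index:
            row["sc_fold"] = sc_fold_change(means[CONTROL], means[STRESSED])

        rwc_d = rwc[rwc["day"] == day]
        for group, sub in rwc_d.groupby("group"):
            row[f"rwc_{group}"] = sub["rwc_pct"].mean()

        spad_d = spad[spad["day"] == day]
        smeans = spad_d.groupby("group")["value"].mean()
        if spad_reference == "control" and CONTROL in smeans.index:
            ref = smeans[CONTROL]
            for group in smeans.index:
                row[f"relative_spad_{group}"] = relative_spad(smeans[group], ref)
        elif spad_reference == "day0":
            day0 = spad[spad["day"] == sorted(physio["day"].unique())[0]]
            refs = day0.groupby("group")["value"].mean()
            for group in smeans.index:
                if group in refs.index:
                    row[f"relative_spad_{group}"] = relative_spad(
                        smeans[group], refs[group]
                    )
        rows.append(row)
    return pd.DataFrame(rows)
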