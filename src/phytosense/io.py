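"""Table schemas, validated CSV round-trips, provenance and the end-to-end run.

Every pipeline table travels as plain CSV with a declared schema; reads
validate the header and name the offending column on mismatch. ``run_all``
executes simulate -> sensor -> imaging -> physiology -> stats in order into an
output directory and records provenance (tool version, seed, config hash and
per-stage row counts) in ``manifest.json``; a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .design import ExperimentDesign, build_design, design_from_yaml, design_to_yaml
from .imaging import ImagingConfig, SegmentationSpec, extract_indices, indices_to_frame
from .physiology import physio_summary
from .render import render_plant_images
from .sensor import (
    compute_response,
    daily_mean,
    detect_onset,
    normalize_nr,
    recovery_deficit,
    segment_phases,
    subdaily_nr,
)
from .stats import (
    build_feature_table,
    correlation_matrix,
    pc1_group_separation,
    run_pca,
    timepoint_tests,
)
from .synthetic import (
    GeneratorConfig,
    sample_physiology,
    simulate_latent_states,
    synthesize_all_traces,
)

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "RunConfig", "run_all"]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    pass


SCHEMAS: dict[str, list[str]] = {
    "sensor_trace": ["plant_id", "group", "time_min", "i_ds_uA", "i_ds0_uA"],
    "response": ["plant_id", "group", "time_min", "r"],
    "daily_r": ["plant_id", "group", "day", "r_mean", "n_samples", "complete"],
    "daily_nr": ["day", "nr", "n_stressed", "n_control"],
    "physio": ["plant_id", "group", "day", "measure", "replicate", "value"],
    "manifest_images": ["plant_id", "day", "view", "modality", "path"],
    "indices": [
        "plant_id", "day", "biovolume", "height_px", "compactness",
        "green_index", "nir_index",
    ],
    "physio_summary": ["day"],
    "correlations": ["var_a", "var_b", "r", "p", "n"],
    "timepoint_tests": ["day", "variable", "method", "statistic", "p_value", "stars"],
}

_INT_COLUMNS = {"time_min", "day", "replicate", "n_samples", "n_stressed", "n_control"}


def write_table(df: pd.DataFrame, path, schema_id: str) -> Path:
    """Write a schema-checked CSV; integer columns stay integer, floats repr-stable."""
    required = SCHEMAS[schema_id]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema_id}: missing column {missing[0]!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if col in _INT_COLUMNS:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Read a CSV and validate its header against the schema.

    A missing required column raises :class:`SchemaError` naming the column;
    extra columns are preserved with a warning.
    """
    df = pd.read_csv(path)
    required = SCHEMAS[schema_id]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{schema_id}: missing column {col!r} in {path}")
    extra = [c for c in df.columns if c not in required]
    if extra and schema_id != "physio_summary":
        logger.warning("%s: extra columns preserved: %s", schema_id, extra)
    return df


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``design`` is a preset name ("MAIN"/"PILOT"), a path to a design YAML, or
    an :class:`ExperimentDesign`. Generator parameters are overridden via
    ``generator``; ``seed`` feeds every source of randomness.
    """

    design: str | ExperimentDesign = "MAIN"
    generator: dict = field(default_factory=dict)
    seed: int = 0
    window_h: float = 12.0
    alpha: float = 0.05
    green_window_deg: tuple[float, float] = (60.0, 180.0)
    compactness_view: str = "top"
    star_map: str = "conventional"
    test_method: str = "anova"
    write_images: bool = True
    log_level: str = "INFO"

    _KNOWN = {
        "design", "generator", "seed", "window_h", "alpha", "green_window_deg",
        "compactness_view", "star_map", "test_method", "write_images", "log_level",
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "green_window_deg" in doc:
            doc["green_window_deg"] = tuple(doc["green_window_deg"])
        return cls(**doc)

    def resolve_design(self) -> ExperimentDesign:
        if isinstance(self.design, ExperimentDesign):
            return self.design
        if self.design.upper() in ("MAIN", "PILOT"):
            d = build_design(self.design)
        else:
            d = design_from_yaml(self.design)
        gen = self.generator_config()
        if d.sampling_interval_min != gen.sampling_interval_min:
            d = dataclasses.replace(
                d, sampling_interval_min=gen.sampling_interval_min
            )
        return d

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(**{"seed": self.seed, **self.generator})

    def imaging_config(self) -> ImagingConfig:
        return ImagingConfig(
            green_hue_deg=tuple(self.green_window_deg),
            compactness_view=self.compactness_view,
        )

    def config_hash(self) -> str:
        design = self.resolve_design()
        payload = {
            "design": design_to_yaml(design),
            "generator": dataclasses.asdict(self.generator_config()),
            "seed": self.seed,
            "window_h": self.window_h,
            "alpha": self.alpha,
            "green_window_deg": list(self.green_window_deg),
            "compactness_view": self.compactness_view,
            "star_map": self.star_map,
            "test_method": self.test_method,
            "version": __version__,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the full pipeline


def _save_png(array: np.ndarray, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(array).save(path, format="PNG")


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the complete pipeline into ``out_dir``; returns the manifest dict.

    Stage order: simulate latent states and raw data; sensor processing (R,
    daily NR, phases, onset, recovery); image rendering and index extraction;
    physiology summary; integrative statistics. Any stage failure aborts with
    the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.resolve_design()
    gen = config.generator_config()
    manifest: dict = {
        "tool": "phytosense",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "design": design.name,
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        states = simulate_latent_states(gen, design)
        traces = synthesize_all_traces(states, gen, design)
        physio = sample_physiology(states, gen, design)
        write_table(traces, out / "sensor_trace.csv", "sensor_trace")
        write_table(physio, out / "physio.csv", "physio")
        design_to_yaml(design, out / "design.yaml")
        manifest["stages"][stage] = {
            "rows_sensor_trace": len(traces),
            "rows_physio": len(physio),
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "sensor"
        t0 = time.perf_counter()
        response = compute_response(traces)
        write_table(response, out / "response.csv", "response")
        daily = daily_mean(response, design)
        write_table(daily, out / "daily_r.csv", "daily_r")
        nr = normalize_nr(daily)
        write_table(nr, out / "daily_nr.csv", "daily_nr")
        seg = segment_phases(nr, design)
        (out / "phases.json").write_text(
            json.dumps(
                {
                    "k": seg.k,
                    "breakpoints": list(seg.breakpoints),
                    "segments": [
                        {
                            "label": s.label,
                            "start_day": s.start_day,
                            "end_day": s.end_day,
                            "slope": s.slope,
                        }
                        for s in seg.segments
                    ],
                },
                indent=2,
            )
            + "\n"
        )
        nr_fine = subdaily_nr(response)
        onset = detect_onset(nr_fine, design, config.window_h, config.alpha)
        try:
            recovery = recovery_deficit(nr, seg)
        except ValueError:
            recovery = None
        (out / "onset.json").write_text(
            json.dumps(
                {
                    "detected": onset.detected,
                    "onset_h": onset.onset_h,
                    "window_slope": onset.window_slope,
                    "p_slope": onset.p_slope,
                    "recovery_ratio": recovery,
                },
                indent=2,
            )
            + "\n"
        )
        manifest["stages"][stage] = {
            "rows_daily_nr": len(nr),
            "onset_detected": onset.detected,
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "imaging"
        t0 = time.perf_counter()
        img_cfg = config.imaging_config()
        records = []
        manifest_rows = []
        for st in states:
            for day in design.imaging_days:
                iset = render_plant_images(st, gen, day)
                if config.write_images:
                    for (view, modality), arr in sorted(iset.images.items()):
                        rel = f"images/{st.plant_id}_d{day:02d}_{view}_{modality}.png"
                        _save_png(arr, out / rel)
                        manifest_rows.append((st.plant_id, day, view, modality, rel))
                records.append(extract_indices(iset, img_cfg))
        indices = indices_to_frame(records)
        write_table(indices, out / "indices.csv", "indices")
        if manifest_rows:
            write_table(
                pd.DataFrame(
                    manifest_rows,
                    columns=["plant_id", "day", "view", "modality", "path"],
                ),
                out / "image_manifest.csv",
                "manifest_images",
            )
        manifest["stages"][stage] = {"rows_indices": len(indices)}
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "physiology"
        t0 = time.perf_counter()
        summary = physio_summary(physio, design)
        write_table(summary, out / "physio_summary.csv", "physio_summary")
        manifest["stages"][stage] = {"rows_summary": len(summary)}
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        features = build_feature_table(indices, daily, physio)
        features.to_csv(out / "feature_table.csv", index=False, lineterminator="\n")
        corr = correlation_matrix(features)
        write_table(corr, out / "correlations.csv", "correlations")
        pca = run_pca(features)
        pca.scores.to_csv(out / "pca_scores.csv", index=False, lineterminator="\n")
        pca.loadings.to_csv(out / "pca_loadings.csv", lineterminator="\n")
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca.variance_explained))],
                "variance_explained_pct": pca.variance_explained,
            }
        ).to_csv(out / "variance_explained.csv", index=False, lineterminator="\n")
        (out / "biplot.json").write_text(
            json.dumps(pca.biplot_data(), indent=2) + "\n"
        )
        long = features.melt(
            id_vars=["plant_id", "day", "group"],
            value_vars=[c for c in ("C", "GI", "NI", "DB", "R") if c in features],
            var_name="variable",
        ).dropna()
        tests = timepoint_tests(long, config.test_method, config.star_map)
        write_table(tests, out / "timepoint_tests.csv", "timepoint_tests")
        manifest["stages"][stage] = {
            "rows_features": len(features),
            "pc1_separation_sd": pc1_group_separation(pca),
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
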