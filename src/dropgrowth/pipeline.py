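"""Run orchestration: configuration, image I/O, staging and table output.

Binds the stages into the full workflow — generate or ingest images, detect
droplets, quantify per-droplet biomass, derive the day-0 threshold and score
growth across time points — and persists everything as TSV tables plus a
YAML config snapshot and a plain-text log, so a run is reproducible from its
persisted config and seed.

Time points are encoded as hours: either an explicit ``timepoints`` mapping
in the config, or parsed from file names containing ``_t<H>h`` (hours) or
``_d<D>`` (days, converted to hours on ingest).  Images from different stage
positions are treated as independent; droplets seen in overlapping fields
are not deduplicated.
"""

from __future__ import annotations

import dataclasses
import datetime
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import DetectionConfig, DropletROI, detect_droplets, monodispersity_stats
from .errors import ConfigurationError, FormatError, InsufficientDataError, StageError
from .quantification import QuantParams, measure_population
from .scoring import compute_threshold, growth_curve, normalized_growth_score
from .synthetic import (
    DEFAULT_PIXEL_SIZE,
    GrowthModelParams,
    GrowerParams,
    OpticsParams,
    generate_series,
)

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "ImageRecord",
    "read_images",
    "write_tables",
    "run_pipeline",
]

_TIME_HOURS_RE = re.compile(r"_t(\d+(?:\.\d+)?)h")
_TIME_DAYS_RE = re.compile(r"_d(\d+(?:\.\d+)?)(?:\b|_|\.)")

DROPLET_COLUMNS = [
    "image_id", "droplet_id", "row", "col", "radius_px", "diameter_um",
    "excluded", "score",
]
THRESHOLD_COLUMNS = ["value", "day0_mean", "day0_sd", "n_nonzero"]


@dataclass(frozen=True)
class ImageRecord:
    """One ingested image with its acquisition metadata."""

    image_id: str
    image: np.ndarray
    timepoint: float  # hours
    source: str | None = None
    bit_depth: int = 8


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run.

    Exactly one of ``inputs`` (image paths) or ``synthetic`` (generator
    spec: n_droplets, timepoints, optional lambda_/mean_diameter/cv/shape/
    n_scenes/growth/optics) must be provided.  Detection and quantification
    parameter overrides are plain dicts applied on top of the documented
    defaults.
    """

    inputs: list[str] | None = None
    timepoints: dict[str, float] | None = None  # path/image_id -> hours
    synthetic: dict | None = None
    pixel_size: float = DEFAULT_PIXEL_SIZE
    detection: dict = field(default_factory=dict)
    quantification: dict = field(default_factory=dict)
    threshold_policy: str = "day0"
    threshold_override: float | None = None
    normalization_scope: str = "series-global"
    seed: int = 0
    output_dir: str | None = None

    def detection_config(self) -> DetectionConfig:
        kw = dict(self.detection)
        if "radius_range" in kw:
            kw["radius_range"] = tuple(kw["radius_range"])
        return DetectionConfig(**kw)

    def quant_params(self) -> QuantParams:
        return QuantParams(**self.quantification)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError("config YAML must contain a mapping")
        return cls.from_dict(data)


@dataclass
class ResultsBundle:
    """All tables from one run plus the log and the config snapshot."""

    droplets: pd.DataFrame
    measurements: pd.DataFrame
    thresholds: pd.DataFrame
    scores: pd.DataFrame
    log: str
    config: RunConfig


class _RunLog:
    def __init__(self) -> None:
        self._buf = io.StringIO()

    def info(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self._buf.write(f"{stamp} {msg}\n")

    def text(self) -> str:
        return self._buf.getvalue()


def _timepoint_for(name: str, mapping: dict[str, float] | None) -> float:
    if mapping is not None:
        for key, hours in mapping.items():
            if key == name or Path(key).name == Path(name).name:
                return float(hours)
        raise ConfigurationError(f"no timepoint configured for image {name!r}")
    m = _TIME_HOURS_RE.search(name)
    if m:
        return float(m.group(1))
    m = _TIME_DAYS_RE.search(name)
    if m:
        return float(m.group(1)) * 24.0
    raise ConfigurationError(
        f"cannot infer timepoint for {name!r}: use a '_t<H>h' or '_d<D>' "
        "filename or an explicit timepoints mapping"
    )


def read_images(
    paths: list[str], timepoints: dict[str, float] | None = None
) -> list[ImageRecord]:
    """Load single-channel 8/16-bit TIFF or PNG images with metadata.

    Multi-channel (e.g. RGB) images are rejected with a hint to convert to
    grayscale first; the timepoint of each image comes from the mapping or
    the filename convention.
    """
    records = []
    for p in paths:
        path = Path(p)
        if not path.exists():
            raise FormatError(f"input image not found: {p}")
        try:
            if path.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(path)
            elif path.suffix.lower() == ".png":
                arr = iio.imread(path)
            else:
                raise FormatError(
                    f"unsupported image format {path.suffix!r} for {p}; "
                    "use TIFF or PNG"
                )
        except FormatError:
            raise
        except Exception as exc:  # noqa: BLE001 - surface the reader failure
            raise FormatError(f"cannot read image {p}: {exc}") from exc
        if arr.ndim != 2:
            raise FormatError(
                f"image {p} has shape {arr.shape}; expected single-channel "
                "2-D grayscale (convert RGB/multi-channel images first)"
            )
        if arr.dtype == np.uint8:
            depth = 8
        elif arr.dtype == np.uint16:
            depth = 16
        else:
            raise FormatError(
                f"image {p} has dtype {arr.dtype}; expected uint8 or uint16"
            )
        records.append(
            ImageRecord(
                image_id=path.stem,
                image=arr,
                timepoint=_timepoint_for(str(p), timepoints),
                source=str(p),
                bit_depth=depth,
            )
        )
    return records


def _growth_params_from_spec(spec: dict) -> GrowthModelParams:
    g = dict(spec)
    for cls in ("fast", "slow"):
        if cls in g and isinstance(g[cls], dict):
            g[cls] = GrowerParams(**g[cls])
    return GrowthModelParams(**g)


def _synthetic_records(config: RunConfig, log: _RunLog) -> list[ImageRecord]:
    spec = dict(config.synthetic or {})
    n_droplets = int(spec.pop("n_droplets", 12))
    timepoints = [float(t) for t in spec.pop("timepoints", [0.0, 72.0])]
    n_scenes = int(spec.pop("n_scenes", 1))
    growth = _growth_params_from_spec(spec.pop("growth", {}))
    optics = OpticsParams(**spec.pop("optics", {}))
    shape = tuple(spec.pop("shape", (1024, 1024)))
    known = {"lambda_", "mean_diameter", "cv"}
    extra = set(spec) - known
    if extra:
        raise ConfigurationError(f"unknown synthetic spec keys: {sorted(extra)}")
    records = []
    for s in range(n_scenes):
        scenes = generate_series(
            n_droplets,
            seed=config.seed + 1009 * s,
            timepoints=timepoints,
            pixel_size=config.pixel_size,
            shape=shape,
            growth=growth,
            optics=optics,
            **spec,
        )
        for scene in scenes:
            records.append(
                ImageRecord(
                    image_id=f"synthetic_s{s}_t{scene.timepoint:g}h",
                    image=scene.image,
                    timepoint=scene.timepoint,
                    source=None,
                    bit_depth=optics.bit_depth,
                )
            )
    log.info(
        f"generated {len(records)} synthetic scene(s): {n_scenes} cohort(s) "
        f"x {len(timepoints)} timepoint(s), {n_droplets} droplets each"
    )
    return records


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute detect → quantify → threshold → score and collect all tables.

    Deterministic given the config and seed; raises
    :class:`ConfigurationError` for invalid configs and :class:`StageError`
    (naming the stage and input) for per-stage failures.  Tables are written
    to ``config.output_dir`` when set.
    """
    log = _RunLog()
    if (config.inputs is None) == (config.synthetic is None):
        raise ConfigurationError(
            "exactly one of 'inputs' or 'synthetic' must be provided"
        )
    det_cfg = config.detection_config()
    quant = config.quant_params()
    log.info(f"effective detection config: {det_cfg}")
    log.info(f"effective quantification params: {quant}")
    log.info(f"pixel size: {config.pixel_size} um/px; seed: {config.seed}")

    if config.inputs is not None:
        records = read_images(config.inputs, config.timepoints)
        log.info(f"loaded {len(records)} image(s)")
    else:
        records = _synthetic_records(config, log)

    droplet_rows = []
    rois_by_image: dict[str, list[DropletROI]] = {}
    for rec in records:
        try:
            rois = detect_droplets(rec.image, det_cfg, image_id=rec.image_id)
        except Exception as exc:  # noqa: BLE001
            raise StageError("detect", f"image {rec.image_id!r}: {exc}") from exc
        rois_by_image[rec.image_id] = rois
        for roi in rois:
            droplet_rows.append(
                {
                    "image_id": rec.image_id,
                    "droplet_id": roi.id,
                    "row": roi.center[0],
                    "col": roi.center[1],
                    "radius_px": roi.radius,
                    "diameter_um": 2 * roi.radius * config.pixel_size,
                    "excluded": roi.excluded or "",
                    "score": roi.score,
                }
            )
    droplets_df = pd.DataFrame(droplet_rows, columns=DROPLET_COLUMNS)
    n_kept = int((droplets_df["excluded"] == "").sum()) if len(droplets_df) else 0
    log.info(
        f"detected {len(droplets_df)} droplet(s), {n_kept} non-excluded"
    )
    all_rois = [r for rois in rois_by_image.values() for r in rois]
    try:
        mono = monodispersity_stats(all_rois, config.pixel_size)
        log.info(
            f"monodispersity: n={mono.n} mean={mono.mean_diameter:.2f} um "
            f"sd={mono.sd_diameter:.2f} um cv={mono.cv:.4f}"
        )
    except InsufficientDataError:
        log.info("monodispersity: skipped (<2 non-excluded droplets)")

    try:
        measurements = measure_population(
            (
                (rec.image, rois_by_image[rec.image_id], rec.image_id, rec.timepoint)
                for rec in records
            ),
            quant,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("measure", str(exc)) from exc
    log.info(f"measured {len(measurements)} droplet(s)")

    times = np.sort(measurements["timepoint"].unique()) if len(measurements) else np.array([])
    try:
        if config.threshold_policy == "day0":
            if times.size == 0 or times[0] != 0:
                raise ConfigurationError(
                    "threshold policy 'day0' requires measurements at 0 h"
                )
            day0 = measurements.loc[
                measurements["timepoint"] == 0, "growth_value"
            ].to_numpy()
            thr = compute_threshold(day0)
        elif config.threshold_policy == "override":
            if config.threshold_override is None:
                raise ConfigurationError(
                    "threshold policy 'override' requires threshold_override"
                )
            thr = None
        else:
            raise ConfigurationError(
                f"unknown threshold policy {config.threshold_policy!r}"
            )
    except ConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("threshold", str(exc)) from exc
    if thr is not None:
        thresholds_df = pd.DataFrame(
            [
                {
                    "value": thr.value,
                    "day0_mean": thr.day0_mean,
                    "day0_sd": thr.day0_sd,
                    "n_nonzero": thr.n_nonzero,
                }
            ],
            columns=THRESHOLD_COLUMNS,
        )
        log.info(
            f"day-0 threshold: {thr.value:.6g} (mean {thr.day0_mean:.6g} "
            f"+ 2 x sd {thr.day0_sd:.6g}, n={thr.n_nonzero})"
        )
    else:
        thresholds_df = pd.DataFrame(
            [{"value": config.threshold_override, "day0_mean": np.nan,
              "day0_sd": np.nan, "n_nonzero": 0}],
            columns=THRESHOLD_COLUMNS,
        )
        log.info(f"override threshold: {config.threshold_override:.6g}")

    try:
        if times.size >= 2:
            scores_df = growth_curve(
                measurements,
                threshold_policy=config.threshold_policy,
                threshold_override=config.threshold_override,
                scope=config.normalization_scope,
            )
        else:
            t0 = float(times[0]) if times.size else 0.0
            thr_value = (
                thr if thr is not None else float(config.threshold_override)
            )
            s = normalized_growth_score(
                measurements["growth_value"].to_numpy(), thr_value, timepoint=t0
            )
            scores_df = pd.DataFrame(
                [
                    {
                        "timepoint": t0, "G_A": s.G_A, "N": s.N,
                        "G_A_Max": s.G_A_Max, "score": s.score, "scope": s.scope,
                    }
                ]
            )
    except ConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", str(exc)) from exc
    log.info(f"scored {len(scores_df)} timepoint(s)")

    bundle = ResultsBundle(
        droplets=droplets_df,
        measurements=measurements,
        thresholds=thresholds_df,
        scores=scores_df,
        log=log.text(),
        config=config,
    )
    if config.output_dir is not None:
        write_tables(bundle, config.output_dir)
    return bundle


def write_tables(bundle: ResultsBundle, directory: str) -> dict[str, Path]:
    """Persist all tables as TSV plus config.yaml and run.log.

    TSV: header row, UTF-8, dot decimal separator, floats at 6 significant
    digits.  Returns the written paths keyed by artifact name.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("droplets", bundle.droplets),
        ("measurements", bundle.measurements),
        ("thresholds", bundle.thresholds),
        ("scores", bundle.scores),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g", encoding="utf-8")
        paths[name] = p
    p = out / "config.yaml"
    p.write_text(bundle.config.to_yaml(), encoding="utf-8")
    paths["config"] = p
    p = out / "run.log"
    p.write_text(bundle.log, encoding="utf-8")
    paths["log"] = p
    return paths
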