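"""File formats, run configuration and the end-to-end pipeline driver.

Interchange formats
-------------------
* time stacks: OME-TIFF, TYX order, physical pixel size in µm and frame
  interval in s carried in the OME metadata;
* dynamic images: 3-plane 32-bit float TIFF plus a JSON sidecar (bands,
  acquisition, estimator, seed);
* scenes: JSON (nuclei, transform, parameters) plus label TIFFs;
* landmarks: CSV with columns id, x_a, y_a, z_a, x_b, y_b, z_b (µm);
* transforms: JSON (dimensionality, row-major rotation, translation in µm).

Every artifact written by :func:`run_pipeline` carries a sidecar recording
the inputs, parameters, seed and package version, sufficient to re-run the
producing stage.  Identical config + seed → byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dyncontrast import (
    DEFAULT_BANDS,
    AcquisitionParams,
    BandTriplet,
    DynamicImage,
    TimeStack,
    compute_dffoct,
    compute_static,
    to_rgb,
)
from .phantom import (
    PhantomSpec,
    SceneGroundTruth,
    build_scene,
    render_confocal,
    simulate_timestack,
)
from .quantify import (
    ClassifierParams,
    classify_by_area,
    compartment_summary,
    match_to_ground_truth,
    measure_regions,
    records_frame,
    segment_ganglia,
    segment_nuclei,
    size_histogram,
)

logger = logging.getLogger(__name__)

__all__ = [
    "write_stack",
    "read_stack",
    "write_dynamic",
    "read_dynamic",
    "write_landmarks",
    "read_landmarks",
    "write_scene",
    "RunConfig",
    "run_pipeline",
]

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def write_stack(path: str | Path, stack: TimeStack) -> None:
    """Write a TimeStack as OME-TIFF (TYX, float32) with physical metadata."""
    data = np.asarray(stack.data, dtype=np.float32)
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "TYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": 1.0 / stack.sampling_rate,
            "TimeIncrementUnit": "s",
        },
    )


def read_stack(
    path: str | Path,
    *,
    sampling_rate: float | None = None,
    pixel_size: float | None = None,
) -> TimeStack:
    """Read a time stack from (OME-)TIFF.

    Physical metadata is taken from the OME header; for plain TIFFs the
    ``sampling_rate`` / ``pixel_size`` overrides are mandatory and an error
    names the missing field otherwise.  Explicit overrides always win.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_rate = None
        meta_px = None
        if tif.ome_metadata:
            root = ET.fromstring(tif.ome_metadata)
            pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
            if pixels is not None:
                dims = pixels.get("DimensionOrder", "")
                if dims and not dims.upper().endswith("T") and "T" not in dims.upper():
                    raise ValueError(
                        f"ambiguous axis order {dims!r} in {path.name}"
                    )
                ti = pixels.get("TimeIncrement")
                px = pixels.get("PhysicalSizeX")
                if ti is not None and float(ti) > 0:
                    meta_rate = 1.0 / float(ti)
                if px is not None:
                    meta_px = float(px)
    if data.ndim == 2:
        raise ValueError(f"{path.name}: single frame is not a time stack")
    rate = sampling_rate if sampling_rate is not None else meta_rate
    px_size = pixel_size if pixel_size is not None else meta_px
    if rate is None:
        raise ValueError(
            f"{path.name}: no TimeIncrement metadata; pass sampling_rate="
        )
    if px_size is None:
        raise ValueError(
            f"{path.name}: no PhysicalSizeX metadata; pass pixel_size="
        )
    return TimeStack(data, sampling_rate=rate, pixel_size=px_size)


# ---------------------------------------------------------------------------
# dynamic images
# ---------------------------------------------------------------------------


def write_dynamic(path: str | Path, img: DynamicImage, seed: int | None = None) -> None:
    """3-plane float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        str(path),
        np.asarray(img.channels, dtype=np.float32),
        photometric="minisblack",
    )
    sidecar = {
        "bands_hz": img.bands.as_dict(),
        "pixel_size_um": img.pixel_size,
        "provenance": img.provenance,
        "seed": seed,
        "software_version": __version__,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_dynamic(path: str | Path) -> DynamicImage:
    path = Path(path)
    channels = tifffile.imread(str(path))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    bands_d = sidecar["bands_hz"]
    bands = BandTriplet(
        tuple(bands_d["low"]), tuple(bands_d["medium"]), tuple(bands_d["high"])
    )
    return DynamicImage(
        channels, bands, sidecar["pixel_size_um"], sidecar.get("provenance", {})
    )


# ---------------------------------------------------------------------------
# landmarks, scenes
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["id", "x_a", "y_a", "z_a", "x_b", "y_b", "z_b"]


def write_landmarks(path: str | Path, landmarks: pd.DataFrame) -> None:
    landmarks[LANDMARK_COLUMNS].to_csv(path, index=False)


def read_landmarks(path: str | Path):
    """Load a landmark CSV into a LandmarkSet ((y, x[, z]) point order)."""
    from .registration import LandmarkSet

    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark file missing columns: {sorted(missing)}")
    three_d = (df["z_a"].abs().max() > 0) or (df["z_b"].abs().max() > 0)
    if three_d:
        pts_a = df[["y_a", "x_a", "z_a"]].to_numpy(float)
        pts_b = df[["y_b", "x_b", "z_b"]].to_numpy(float)
    else:
        pts_a = df[["y_a", "x_a"]].to_numpy(float)
        pts_b = df[["y_b", "x_b"]].to_numpy(float)
    return LandmarkSet(pts_a, pts_b, ids=df["id"].tolist())


def write_scene(out_dir: str | Path, scene: SceneGroundTruth) -> None:
    """Scene ground truth as JSON + label TIFFs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(out / "compartments.tif"), scene.compartment_labels)
    tifffile.imwrite(str(out / "nucleus_labels.tif"), scene.nucleus_labels)
    tifffile.imwrite(str(out / "ganglion_labels.tif"), scene.ganglion_labels)
    tifffile.imwrite(
        str(out / "static_template.tif"),
        np.asarray(scene.static_template, dtype=np.float32),
    )
    meta = {
        "pixel_size_um": scene.pixel_size,
        "confocal_transform": scene.confocal_transform.to_dict(),
        "nuclei": [
            {
                "id": n.id,
                "class": n.cls,
                "centroid_um": list(n.centroid_um),
                "semi_axes_um": list(n.semi_axes_um),
                "orientation_rad": n.orientation,
                "analytic_area_um2": n.analytic_area_um2,
                "raster_area_um2": n.raster_area_um2,
                "dropout": n.dropout,
            }
            for n in scene.nuclei
        ],
        "software_version": __version__,
    }
    (out / "scene.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one simulate→analyse run needs, serialisable to YAML."""

    out_dir: Path
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    bands: BandTriplet = field(default_factory=BandTriplet)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    write_stack_file: bool = False  # raw stacks are large; opt in
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        for key in ("seed", "write_stack_file", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            if "field_of_view" in ph:
                ph["field_of_view"] = tuple(ph["field_of_view"])
            kwargs["phantom"] = PhantomSpec(**ph)
        if "acquisition" in raw:
            kwargs["acquisition"] = AcquisitionParams(**raw["acquisition"])
        if "bands" in raw:
            b = raw["bands"]
            kwargs["bands"] = BandTriplet(
                tuple(b["low"]), tuple(b["medium"]), tuple(b["high"])
            )
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierParams(**raw["classifier"])
        if "out_dir" not in kwargs:
            raise ValueError("config must provide out_dir")
        return cls(**kwargs)

    def validate(self) -> None:
        self.acquisition.validate_bands(self.bands)


def _sidecar(path: Path, stage: str, params: dict, seed: int) -> None:
    doc = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "software_version": __version__,
    }
    path.write_text(json.dumps(doc, indent=2, default=str))


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """simulate → dynamic contrast → segment → measure → classify → match.

    Returns a bundle of in-memory results and writes CSV tables plus JSON
    sidecars under ``config.out_dir``.  Deterministic: identical config and
    seed produce byte-identical tables.
    """
    config.validate()
    if dry_run:
        logger.info("dry run: configuration valid")
        return {"dry_run": True}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.phantom, seed=config.seed)

    stage = "simulate"
    try:
        scene = build_scene(spec)
        stack = simulate_timestack(scene, spec, config.acquisition, config.bands)
        write_scene(out / "scene", scene)
        if config.write_stack_file:
            write_stack(out / "stack.ome.tif", stack)
        confocal = render_confocal(
            scene, rng=np.random.default_rng(
                np.random.SeedSequence([config.seed, 2])
            ),
        )
        from .io import write_landmarks as _wl  # self-import for clarity

        _wl(out / "landmarks.csv", confocal.landmarks)
        _sidecar(out / "simulate.json", stage,
                 {"phantom": dataclasses.asdict(spec)}, config.seed)

        stage = "dffoct"
        dyn = compute_dffoct(stack, config.acquisition, config.bands)
        static = compute_static(stack)
        write_dynamic(out / "dynamic.tif", dyn, seed=config.seed)
        tifffile.imwrite(
            str(out / "static.tif"), np.asarray(static, dtype=np.float32)
        )
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(out / "dynamic_rgb.png", to_rgb(dyn))

        stage = "quantify"
        ganglia = segment_ganglia(static, dyn)
        labels = segment_nuclei(dyn, ganglia)
        tifffile.imwrite(str(out / "nucleus_labels.tif"), labels)
        tifffile.imwrite(str(out / "ganglion_labels.tif"), ganglia)
        records = measure_regions(labels, dyn)
        classify_by_area(records, config.classifier)
        detection = match_to_ground_truth(records, scene)
        table = records_frame(records)
        table.to_csv(out / "nuclei.csv", index=False)
        detection.to_csv(out / "detection.csv", index=False)
        hist = size_histogram(records)
        hist.to_csv(out / "size_histogram.csv", index=False)
        comp = None
        for box_um in (20.0, 10.0, 5.0):  # shrink boxes on small fields
            try:
                comp = compartment_summary(
                    dyn, ganglia, box_um=box_um,
                    rng=np.random.default_rng(
                        np.random.SeedSequence([config.seed, 3])
                    ),
                )
                break
            except ValueError:
                continue
        if comp is None:
            raise ValueError("could not place compartment regions")
        comp.table.to_csv(out / "compartments.csv", index=False)
        _sidecar(
            out / "quantify.json", stage,
            {
                "classifier": dataclasses.asdict(config.classifier),
                "compartment_p_values": comp.p_values,
            },
            config.seed,
        )
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "scene": scene,
        "stack": stack,
        "dynamic": dyn,
        "static": static,
        "ganglion_labels": ganglia,
        "nucleus_labels": labels,
        "records": records,
        "detection": detection,
        "compartments": comp,
        "out_dir": out,
    }
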