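"""Segmentation, nuclear morphometry and compartment statistics.

Workflow on a pair of co-registered images (static contrast + three-band
dynamic contrast):

* ganglia are segmented where the static signal is low (the plexus is a dark
  network) AND the total dynamic power is high;
* nuclei are segmented inside ganglion masks from the combined medium+high
  channels (smooth → threshold → fill → distance-transform watershed →
  area filter);
* each labelled region becomes a :class:`NucleusRecord` carrying its area in
  µm² and its per-band mean intensity measured on the raw float channels;
* nuclei are classified neuron vs glia by an area cutoff (65 µm² by
  default — enteric neuron nuclei are nearly twice the size of glial ones);
* detections are matched one-to-one to ground-truth centroids when a
  synthetic scene is available, yielding per-class detection percentages.

The trainable-segmentation step used interactively on the instrument is
replaced by this deterministic classical pipeline; any externally produced
mask or label image can be substituted through the bypass arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as _stats
from skimage import filters as _filters
from skimage import measure as _measure
from skimage import morphology as _morph
from skimage import segmentation as _seg

from .dyncontrast import BAND_NAMES, DynamicImage
from .phantom import SceneGroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusRecord",
    "ClassifierParams",
    "CompartmentSummary",
    "segment_ganglia",
    "segment_nuclei",
    "measure_regions",
    "classify_by_area",
    "records_frame",
    "match_to_ground_truth",
    "size_histogram",
    "compartment_summary",
]


@dataclass
class NucleusRecord:
    """One segmented nuclear region."""

    id: int
    centroid_um: tuple[float, float]  # (y, x)
    area_um2: float
    mean_low: float
    mean_medium: float
    mean_high: float
    predicted_class: str | None = None  # "neuron" | "glia"
    matched_gt_id: int | None = None

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area must be > 0")
        if min(self.mean_low, self.mean_medium, self.mean_high) < 0:
            raise ValueError("band intensities must be >= 0")


@dataclass(frozen=True)
class ClassifierParams:
    """Area-threshold classifier: area below the cutoff → glia, at or above
    → neuron (the boundary goes to the neuron side by default)."""

    area_cutoff_um2: float = 65.0
    boundary_class: str = "neuron"

    def __post_init__(self) -> None:
        if self.area_cutoff_um2 <= 0:
            raise ValueError("area cutoff must be > 0")
        if self.boundary_class not in ("neuron", "glia"):
            raise ValueError("boundary_class must be 'neuron' or 'glia'")


@dataclass
class CompartmentSummary:
    """Per-compartment × band mean intensity with SEM and group comparison."""

    table: pd.DataFrame  # columns: compartment, band, mean, sem, n
    p_values: dict[str, float]  # band → two-sided Mann-Whitney p (intra vs extra)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_ganglia(
    static: np.ndarray,
    dynamic: DynamicImage,
    *,
    min_area_um2: float = 400.0,
    closing_radius_px: int = 3,
    manual_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Label image of ganglion candidates (0 = background).

    A ganglion is dark in the static image and dynamically bright; both
    criteria use Otsu thresholds on their own image.  ``manual_mask`` (bool
    or label image) bypasses the automation and is returned labelled
    verbatim, mirroring the manual-outline path of the original analysis.
    """
    if manual_mask is not None:
        mm = np.asarray(manual_mask)
        if mm.dtype == bool:
            labels, _ = ndi.label(mm)
            return labels.astype(np.int32)
        return mm.astype(np.int32)
    static = np.asarray(static, dtype=float)
    total = dynamic.total
    if static.shape != total.shape:
        raise ValueError("static and dynamic images must share shape")
    if static.max() == static.min() or total.max() == total.min():
        logger.warning("segment_ganglia: uniform input image(s); empty mask set")
        return np.zeros(static.shape, dtype=np.int32)
    dark = static < _filters.threshold_otsu(static)
    # dynamic power spans orders of magnitude (nuclei >> cytoplasm >>
    # background); threshold on the log scale so the split falls between
    # ganglionic tissue and background, not between nuclei and the rest
    log_total = np.log10(total + 1e-12)
    busy = log_total > _filters.threshold_otsu(log_total)
    mask = dark & busy
    selem = _morph.disk(closing_radius_px)
    mask = ndi.binary_closing(mask, structure=selem)
    mask = ndi.binary_fill_holes(mask)
    # thin interganglionic tracts are plexus, not ganglia: cut them with an
    # opening whose radius exceeds the tract half-width
    mask = ndi.binary_opening(mask, structure=_morph.disk(5))
    min_px = int(round(min_area_um2 / dynamic.pixel_size**2))
    labels, n_lab = ndi.label(mask)
    if n_lab:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_px)[0]
        mask &= ~np.isin(labels, small)
    if not mask.any():
        logger.warning("segment_ganglia: no component above %g µm²", min_area_um2)
        return np.zeros(static.shape, dtype=np.int32)
    labels, _ = ndi.label(mask)
    return labels.astype(np.int32)


def segment_nuclei(
    dynamic: DynamicImage,
    ganglion_labels: np.ndarray,
    *,
    smoothing_sigma_px: float = 0.8,
    threshold: str | float = "isodata",
    area_bounds_um2: tuple[float, float] = (20.0, 300.0),
    min_peak_distance_px: int = 4,
    h_maxima: float | None = 1.0,
) -> np.ndarray:
    """Labelled nucleus regions inside ganglion masks (0 = background).

    Pipeline: combine medium+high channels → Gaussian smoothing → blob
    detection by a global threshold on the *log* power inside the ganglion
    mask (isodata by default, which on the log scale separates nuclei of
    both classes from cytoplasm; "otsu" or a fixed float on the linear scale
    are accepted) → hole filling → distance-transform watershed seeded at
    h-maxima → per-blob boundary refinement at the local class-mean midpoint
    (the half-max contour of a smoothed step edge, which localises the true
    boundary without bias) → area filter.  Candidate blobs outside the
    ganglion mask are counted and logged but never reported: in this tissue
    no dynamically visible nucleus lies outside a ganglion.
    """
    gmask = np.asarray(ganglion_labels) > 0
    combined = dynamic.medium + dynamic.high
    if combined.shape != gmask.shape:
        raise ValueError("dynamic image and ganglion labels must share shape")
    if not np.any(combined > 0):
        return np.zeros(combined.shape, dtype=np.int32)
    smooth = ndi.gaussian_filter(combined.astype(float), smoothing_sigma_px)

    if isinstance(threshold, (int, float)):
        fg = smooth > float(threshold)
    else:
        values = smooth[gmask] if gmask.any() else smooth.ravel()
        if values.size == 0 or values.max() == values.min():
            return np.zeros(combined.shape, dtype=np.int32)
        log_vals = np.log10(np.clip(values, 1e-12, None))
        log_img = np.log10(np.clip(smooth, 1e-12, None))
        if threshold == "isodata":
            fg = log_img > float(_filters.threshold_isodata(log_vals))
        elif threshold == "otsu":
            fg = log_img > float(_filters.threshold_otsu(log_vals))
        else:
            raise ValueError(f"unknown threshold {threshold!r}")
    outside = fg & ~gmask
    if outside.any():
        _, n_out = ndi.label(outside)
        logger.info(
            "segment_nuclei: %d candidate blob(s) outside ganglia suppressed",
            n_out,
        )
    fg &= gmask
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(combined.shape, dtype=np.int32)

    dist = ndi.gaussian_filter(ndi.distance_transform_edt(fg), 1.0)
    if h_maxima is not None and h_maxima > 0:
        peaks = _morph.h_maxima(dist, h_maxima)
    else:
        from skimage.feature import peak_local_max

        peaks = np.zeros_like(fg)
        coords = peak_local_max(
            dist, min_distance=min_peak_distance_px, labels=fg
        )
        peaks[tuple(coords.T)] = True
    markers, n_markers = ndi.label(peaks)
    labels = _seg.watershed(-dist, markers, mask=fg)
    # a compact blob whose distance peak is lower than h gets no marker and
    # would silently vanish; give each orphan component its own label
    comp, n_comp = ndi.label(fg)
    orphan_ids = np.setdiff1d(
        np.unique(comp[fg & (labels == 0)]), [0]
    )
    next_label = int(labels.max()) + 1
    for cid in orphan_ids:
        labels[(comp == cid) & (labels == 0)] = next_label
        next_label += 1

    labels = _refine_boundaries(labels, smooth, gmask)

    px2 = dynamic.pixel_size**2
    lo, hi = area_bounds_um2
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for region in _measure.regionprops(labels):
        area = region.area * px2
        if lo <= area <= hi:
            out[labels == region.label] = next_id
            next_id += 1
    return out


def _refine_boundaries(
    labels: np.ndarray,
    smooth: np.ndarray,
    gmask: np.ndarray,
    pad_px: int = 4,
    n_iter: int = 2,
) -> np.ndarray:
    """Re-threshold each blob at the midpoint of its own foreground and local
    background means.

    A Gaussian-smoothed step edge crosses the mean of its two plateau levels
    exactly at the original step location, so the midpoint contour recovers
    the unbiased nucleus boundary regardless of where the global detection
    threshold happened to fall.
    """
    out = np.zeros_like(labels, dtype=np.int32)
    for region in _measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        y0, x0 = max(0, y0 - pad_px), max(0, x0 - pad_px)
        y1 = min(labels.shape[0], y1 + pad_px)
        x1 = min(labels.shape[1], x1 + pad_px)
        box = (slice(y0, y1), slice(x0, x1))
        sm = smooth[box]
        blob = labels[box] == region.label
        other = (labels[box] > 0) & ~blob
        local_bg = gmask[box] & ~blob & ~other
        if not local_bg.any():
            out[box][blob] = region.label
            continue
        refined = blob
        for _ in range(n_iter):
            fg_mean = sm[refined].mean() if refined.any() else sm[blob].mean()
            bg_mean = sm[local_bg & ~refined].mean() if (local_bg & ~refined).any() else sm[local_bg].mean()
            cand = (sm > 0.5 * (fg_mean + bg_mean)) & gmask[box] & ~other
            cand_lab, n_comp = ndi.label(cand)
            if n_comp == 0:
                break
            hits = np.unique(cand_lab[blob])
            hits = hits[hits > 0]
            if len(hits) == 0:
                break
            refined = np.isin(cand_lab, hits)
        out[box][refined & ~other] = region.label
    return out


# ---------------------------------------------------------------------------
# measurement and classification
# ---------------------------------------------------------------------------


def measure_regions(
    labels: np.ndarray,
    dynamic: DynamicImage,
    pixel_size: float | None = None,
) -> list[NucleusRecord]:
    """Area and raw per-band mean intensity for every labelled region."""
    labels = np.asarray(labels)
    if labels.shape != dynamic.channels.shape[1:]:
        raise ValueError("label image and channels must share shape")
    px = dynamic.pixel_size if pixel_size is None else pixel_size
    records: list[NucleusRecord] = []
    for region in _measure.regionprops(labels):
        if region.area == 0:  # pragma: no cover - regionprops skips these
            logger.warning("label %d has zero pixels; skipped", region.label)
            continue
        mask = labels == region.label
        means = [float(dynamic.channels[b][mask].mean()) for b in range(3)]
        cy, cx = region.centroid
        records.append(
            NucleusRecord(
                id=int(region.label),
                centroid_um=(cy * px, cx * px),
                area_um2=float(region.area) * px * px,
                mean_low=means[0],
                mean_medium=means[1],
                mean_high=means[2],
            )
        )
    return records


def classify_by_area(
    records: Sequence[NucleusRecord],
    params: ClassifierParams = ClassifierParams(),
) -> list[NucleusRecord]:
    """Assign neuron/glia labels in place by the area cutoff; returns records."""
    other = "glia" if params.boundary_class == "neuron" else "neuron"
    for rec in records:
        if rec.area_um2 > params.area_cutoff_um2:
            rec.predicted_class = "neuron"
        elif rec.area_um2 < params.area_cutoff_um2:
            rec.predicted_class = "glia"
        else:
            rec.predicted_class = params.boundary_class
    return list(records)


def records_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    """Tidy table of nucleus records (one row per nucleus)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "y_um": [r.centroid_um[0] for r in records],
            "x_um": [r.centroid_um[1] for r in records],
            "area_um2": [r.area_um2 for r in records],
            "mean_low": [r.mean_low for r in records],
            "mean_medium": [r.mean_medium for r in records],
            "mean_high": [r.mean_high for r in records],
            "predicted_class": [r.predicted_class for r in records],
            "matched_gt_id": [r.matched_gt_id for r in records],
        }
    )


# ---------------------------------------------------------------------------
# ground-truth matching and summaries
# ---------------------------------------------------------------------------


def detection_report(
    detected: dict[str, int], totals: dict[str, int]
) -> pd.DataFrame:
    """Per-class detected/total table with exact and rounded percentages."""
    rows = []
    for cls in sorted(totals):
        n_det = detected.get(cls, 0)
        n_tot = totals[cls]
        pct = 100.0 * n_det / n_tot if n_tot else 0.0
        rows.append(
            {
                "class": cls,
                "detected": n_det,
                "total": n_tot,
                "percent": pct,
                "percent_rounded": int(round(pct)),
            }
        )
    return pd.DataFrame(rows)


def match_to_ground_truth(
    records: Sequence[NucleusRecord],
    scene: SceneGroundTruth,
    max_dist_um: float = 5.0,
) -> pd.DataFrame:
    """Greedy one-to-one nearest-centroid matching against the scene.

    Pairs are accepted closest-first within ``max_dist_um``; every record
    gets its ``matched_gt_id`` set (or None).  Returns the per-class
    detection table from :func:`detection_report`.
    """
    gt = scene.nuclei
    totals = {cls: sum(1 for n in gt if n.cls == cls) for cls in ("neuron", "glia")}
    if not records or not gt:
        return detection_report({}, totals)
    det_c = np.array([r.centroid_um for r in records])
    gt_c = np.array([n.centroid_um for n in gt])
    d = np.linalg.norm(det_c[:, None, :] - gt_c[None, :, :], axis=2)
    order = np.argsort(d, axis=None)
    used_det: set[int] = set()
    used_gt: set[int] = set()
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > max_dist_um:
            break
        if i in used_det or j in used_gt:
            continue
        used_det.add(int(i))
        used_gt.add(int(j))
        records[i].matched_gt_id = gt[j].id
    detected = {
        cls: sum(1 for j in used_gt if gt[j].cls == cls)
        for cls in ("neuron", "glia")
    }
    return detection_report(detected, totals)


def size_histogram(
    records: Sequence[NucleusRecord],
    bin_width_um2: float = 10.0,
    class_field: str = "predicted_class",
) -> pd.DataFrame:
    """Per-class size-frequency distribution with bin edges at multiples of
    ``bin_width_um2``."""
    if bin_width_um2 <= 0:
        raise ValueError("bin_width must be > 0")
    if not records:
        return pd.DataFrame(columns=["bin_left", "bin_right", "class", "count"])
    areas = np.array([r.area_um2 for r in records])
    classes = [getattr(r, class_field) for r in records]
    top = np.ceil(areas.max() / bin_width_um2) * bin_width_um2
    edges = np.arange(0.0, top + bin_width_um2, bin_width_um2)
    rows = []
    for cls in sorted(set(classes), key=str):
        sel = np.array([c == cls for c in classes])
        counts, _ = np.histogram(areas[sel], bins=edges)
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"bin_left": left, "bin_right": right, "class": cls,
                 "count": int(count)}
            )
    return pd.DataFrame(rows)


def _sample_region_boxes(
    allowed: np.ndarray,
    n_regions: int,
    box_px: int,
    rng: np.random.Generator,
    max_tries: int = 5000,
) -> list[tuple[int, int]]:
    """Top-left corners of non-overlapping box regions fully inside a mask."""
    eroded = ndi.binary_erosion(
        allowed, structure=np.ones((box_px, box_px), dtype=bool)
    )
    ys, xs = np.nonzero(eroded)
    if len(ys) == 0:
        raise ValueError(
            f"insufficient area for a {box_px}x{box_px} px region: need "
            f"{box_px * box_px} px contiguous, available mask {int(allowed.sum())} px"
        )
    corners: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(corners) == n_regions:
            break
        j = rng.integers(len(ys))
        cy, cx = int(ys[j]) - box_px // 2, int(xs[j]) - box_px // 2
        if any(abs(cy - oy) < box_px and abs(cx - ox) < box_px
               for oy, ox in corners):
            continue
        corners.append((cy, cx))
    if len(corners) < n_regions:
        raise ValueError(
            f"could only place {len(corners)} of {n_regions} "
            f"{box_px}x{box_px} px regions in {int(allowed.sum())} px of mask"
        )
    return corners


def compartment_summary(
    dynamic: DynamicImage,
    ganglion_labels: np.ndarray,
    n_regions: int = 5,
    *,
    box_um: float = 20.0,
    rng: np.random.Generator | None = None,
    border_um: float = 5.0,
) -> CompartmentSummary:
    """Intra- vs extra-ganglionic band intensities from sampled square regions.

    ``n_regions`` equal-sized boxes are placed inside the ganglion masks and
    another ``n_regions`` outside (with a safety border around the ganglia);
    per-band region means feed a mean ± SEM summary and a two-sided
    Mann-Whitney comparison per band.  With a single region per compartment
    the SEM is reported as missing (NaN), never as zero.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    px = dynamic.pixel_size
    box_px = max(2, int(round(box_um / px)))
    gmask = np.asarray(ganglion_labels) > 0
    border_px = max(1, int(round(border_um / px)))
    extra = ~ndi.binary_dilation(gmask, iterations=border_px)

    means = {"intra": [], "extra": []}
    for comp, allowed in (("intra", gmask), ("extra", extra)):
        corners = _sample_region_boxes(allowed, n_regions, box_px, rng)
        for cy, cx in corners:
            sl = (slice(cy, cy + box_px), slice(cx, cx + box_px))
            means[comp].append(
                [float(dynamic.channels[b][sl].mean()) for b in range(3)]
            )
    rows = []
    p_values: dict[str, float] = {}
    for b, band in enumerate(BAND_NAMES):
        for comp in ("intra", "extra"):
            vals = np.array([m[b] for m in means[comp]])
            sem = (
                float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan")
            )
            rows.append(
                {
                    "compartment": comp,
                    "band": band,
                    "mean": float(vals.mean()),
                    "sem": sem,
                    "n": len(vals),
                }
            )
        intra = np.array([m[b] for m in means["intra"]])
        extra_v = np.array([m[b] for m in means["extra"]])
        if len(intra) > 1 and len(extra_v) > 1:
            p_values[band] = float(
                _stats.mannwhitneyu(intra, extra_v, alternative="two-sided").pvalue
            )
        else:
            p_values[band] = float("nan")
    return CompartmentSummary(pd.DataFrame(rows), p_values)
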