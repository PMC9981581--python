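"""Treatment-response quantification and nonparametric group statistics.

Responses to bath-applied drugs (veratridine, TTX, mannitol) are expressed
as T1:T0 ratios of per-band mean intensity, in percent (100 = no change),
measured either over whole-ganglion masks or per nucleus using the baseline
(T0) nucleus labels applied to every time point.  The statistical unit for
nuclear analyses is the ganglion: per-nucleus ratios are averaged within
each ganglion before any test, so nuclei never pseudo-replicate.  Size-split
variants use the 65 µm² neuron/glia boundary.  Group comparisons use the
exact two-sided Mann-Whitney test; dose-response designs use Kruskal-Wallis
followed by Dunn's post-hoc versus control with Holm adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .dyncontrast import BAND_NAMES, DynamicImage
from .quantify import NucleusRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentExperiment",
    "ResponseRecord",
    "ratio_percent",
    "per_nucleus_response",
    "compare_two_groups",
    "dose_response",
]

SIZE_CUTOFF_UM2 = 65.0


@dataclass
class TreatmentExperiment:
    """Registered dynamic images at T0/T1(/T2) plus the T0 segmentation.

    ``nucleus_to_ganglion`` maps each T0 nucleus label to the ganglion it
    belongs to; ``records`` carry the T0 areas used for size splits.
    ``t1_labels`` (optional) is an independent segmentation of T1 used only
    to count emergent nuclei (absent at T0, hence without a ratio).
    """

    condition: str
    dyn_t0: DynamicImage
    dyn_t1: DynamicImage
    ganglion_labels: np.ndarray
    nucleus_labels: np.ndarray
    records: Sequence[NucleusRecord]
    dyn_t2: DynamicImage | None = None
    t1_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.dyn_t0.channels.shape
        for img in (self.dyn_t1, self.dyn_t2):
            if img is not None and img.channels.shape != shape:
                raise ValueError("time-point images must share shape and frame")
        if np.asarray(self.nucleus_labels).shape != shape[1:]:
            raise ValueError("nucleus labels must match the image grid")


@dataclass
class ResponseRecord:
    """One unit × band response (percent of baseline)."""

    unit: str  # "ganglion" | "nucleus"
    unit_id: int
    band: str
    ratio_t1_t0: float  # percent; 100 = no change
    ratio_t2_t0: float | None = None
    size_class: str = "whole"  # "whole" | ">65" | "<65"


def _band_ratio(img_num: DynamicImage, img_den: DynamicImage,
                mask: np.ndarray) -> list[float]:
    out = []
    for b, band in enumerate(BAND_NAMES):
        num = float(img_num.channels[b][mask].mean())
        den = float(img_den.channels[b][mask].mean())
        if den == 0.0:
            warnings.warn(
                f"T0 mean is zero in band {band!r}; ratio reported missing"
            )
            out.append(float("nan"))
        else:
            out.append(100.0 * num / den)
    return out


def ratio_percent(
    img_t1: DynamicImage,
    img_t0: DynamicImage,
    mask: np.ndarray,
) -> dict[str, float]:
    """Per-band 100 × mean(T1)/mean(T0) over a mask.

    A zero T0 mean yields NaN for that band with a warning, never a crash.
    """
    mask = np.asarray(mask, dtype=bool)
    if img_t1.channels.shape != img_t0.channels.shape:
        raise ValueError("T0 and T1 images must share shape")
    if mask.shape != img_t0.channels.shape[1:]:
        raise ValueError("mask must match the image grid")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = _band_ratio(img_t1, img_t0, mask)
    return dict(zip(BAND_NAMES, vals))


def per_nucleus_response(experiment: TreatmentExperiment) -> tuple[
    pd.DataFrame, pd.DataFrame, int
]:
    """Per-nucleus T1:T0 (and T2:T0) ratios aggregated to ganglion level.

    Returns ``(ganglion_table, nucleus_table, n_emergent)``:

    * ``ganglion_table`` — one row per ganglion × band × size class with the
      mean of its member nuclei's ratios (the statistical unit);
    * ``nucleus_table`` — the underlying per-nucleus ratios (pseudo-replicated
      if tested directly; exposed for inspection);
    * ``n_emergent`` — nuclei present in ``t1_labels`` with no T0 counterpart
      (no T0 denominator exists, so they are counted, not ratioed).
    """
    exp = experiment
    nuc_labels = np.asarray(exp.nucleus_labels)
    gang_labels = np.asarray(exp.ganglion_labels)
    by_id = {r.id: r for r in exp.records}

    nuc_rows = []
    for nid in np.unique(nuc_labels):
        if nid == 0:
            continue
        mask = nuc_labels == nid
        rec = by_id.get(int(nid))
        area = rec.area_um2 if rec is not None else float("nan")
        glabels, counts = np.unique(gang_labels[mask], return_counts=True)
        gid = int(glabels[np.argmax(counts)])
        if gid == 0:
            logger.info("nucleus %d lies outside ganglion masks; excluded", nid)
            continue
        r1 = _band_ratio(exp.dyn_t1, exp.dyn_t0, mask)
        r2 = (
            _band_ratio(exp.dyn_t2, exp.dyn_t0, mask)
            if exp.dyn_t2 is not None
            else [None] * 3
        )
        for b, band in enumerate(BAND_NAMES):
            nuc_rows.append(
                {
                    "nucleus_id": int(nid),
                    "ganglion_id": gid,
                    "band": band,
                    "area_um2": area,
                    "ratio_t1_t0": r1[b],
                    "ratio_t2_t0": r2[b],
                }
            )
    nucleus_table = pd.DataFrame(nuc_rows)

    gang_rows = []
    if not nucleus_table.empty:
        def _size_sel(df: pd.DataFrame, size_class: str) -> pd.Series:
            if size_class == "whole":
                return pd.Series(True, index=df.index)
            if size_class == ">65":
                return df["area_um2"] > SIZE_CUTOFF_UM2
            return df["area_um2"] < SIZE_CUTOFF_UM2

        for size_class in ("whole", ">65", "<65"):
            sel = nucleus_table[_size_sel(nucleus_table, size_class)]
            grouped = sel.groupby(["ganglion_id", "band"])
            for (gid, band), grp in grouped:
                t2_vals = grp["ratio_t2_t0"].dropna()
                gang_rows.append(
                    {
                        "ganglion_id": int(gid),
                        "band": band,
                        "size_class": size_class,
                        "n_nuclei": len(grp),
                        "ratio_t1_t0": float(grp["ratio_t1_t0"].mean()),
                        "ratio_t2_t0": (
                            float(t2_vals.mean()) if len(t2_vals) else None
                        ),
                    }
                )
    ganglion_table = pd.DataFrame(gang_rows)

    n_emergent = 0
    if exp.t1_labels is not None:
        t1_labels = np.asarray(exp.t1_labels)
        for nid in np.unique(t1_labels):
            if nid == 0:
                continue
            mask = t1_labels == nid
            # emergent = no overlap with any T0 nucleus
            if not (nuc_labels[mask] > 0).any():
                n_emergent += 1
    return ganglion_table, nucleus_table, n_emergent


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def compare_two_groups(
    treated: Sequence[float],
    control: Sequence[float],
) -> dict[str, float | str]:
    """Exact two-sided Mann-Whitney comparison of two groups of units.

    scipy switches from the exact null distribution to the normal
    approximation automatically for larger samples or ties.  All-tied inputs
    return p = 1 with a note.  The effect direction reported is the sign of
    median(treated) − median(control).
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 units per group")
    note = ""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return {
            "U": float(len(x) * len(y) / 2),
            "p": 1.0,
            "direction": "none",
            "note": "all observations tied",
        }
    res = _stats.mannwhitneyu(x, y, alternative="two-sided")
    diff = float(np.median(x) - np.median(y))
    direction = "increase" if diff > 0 else ("decrease" if diff < 0 else "none")
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "direction": direction, "note": note}


def _dunn_vs_control(
    groups: Mapping[str, Sequence[float]],
    control_key: str,
    adjust: str = "holm",
) -> dict[str, float]:
    """Dunn's rank-sum post-hoc of every group against the control.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) ) with the
    standard tie correction T = Σ(t³−t) / (12(N−1)); two-sided p-values are
    multiplicity-adjusted (Holm by default; "bonferroni" or "none").
    """
    keys = list(groups)
    all_vals = np.concatenate([np.asarray(groups[k], float) for k in keys])
    n_total = len(all_vals)
    ranks = _stats.rankdata(all_vals)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for k in keys:
        n_k = len(groups[k])
        mean_ranks[k] = float(ranks[start : start + n_k].mean())
        sizes[k] = n_k
        start += n_k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    p_raw = []
    others = [k for k in keys if k != control_key]
    for k in others:
        se = np.sqrt(var_base * (1.0 / sizes[k] + 1.0 / sizes[control_key]))
        if se == 0:
            p_raw.append(1.0)
            continue
        z = (mean_ranks[k] - mean_ranks[control_key]) / se
        p_raw.append(float(2.0 * _stats.norm.sf(abs(z))))
    if adjust == "none":
        p_adj = p_raw
    else:
        p_adj = multipletests(p_raw, method=adjust)[1].tolist()
    return dict(zip(others, p_adj))


def dose_response(
    groups: Mapping[str, Sequence[float]],
    control_key: str | None = None,
    *,
    adjust: str = "holm",
) -> dict:
    """Omnibus Kruskal-Wallis + Dunn's post-hoc vs control + trend summary.

    ``groups`` maps dose labels (insertion order = dose order) to unit-level
    ratios.  Returns H, the omnibus p, adjusted pairwise p-values against the
    control (first key by default), the group medians in dose order, and
    whether those medians decrease/increase monotonically.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("dose_response needs at least 2 groups")
    for k in keys:
        if len(groups[k]) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 units")
    if control_key is None:
        control_key = keys[0]
    if control_key not in groups:
        raise ValueError(f"control key {control_key!r} not among groups")
    arrays = [np.asarray(groups[k], float) for k in keys]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = _stats.kruskal(*arrays)
    medians = {k: float(np.median(groups[k])) for k in keys}
    med_seq = [medians[k] for k in keys]
    diffs = np.diff(med_seq)
    trend = (
        "decreasing" if np.all(diffs < 0)
        else "increasing" if np.all(diffs > 0)
        else "non-monotone"
    )
    return {
        "H": float(h_stat),
        "p_omnibus": float(p_omni),
        "pairwise_vs_control": _dunn_vs_control(groups, control_key, adjust),
        "medians": medians,
        "median_trend": trend,
        "control": control_key,
    }
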