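"""In-silico pharmacology experiments on the synthetic whole-mount.

Each experiment mirrors one of the study's treatment designs: baseline
imaging (T0), 30 min of drug (T1), optional Krebs washout (T2).  A replicate
is one phantom: the scene is built once, the baseline stack is simulated
from it, the treated stack re-uses the same scene with the treatment-scaled
fluctuation spectra (and, for veratridine, rescued dropout nuclei), and the
washout stack restores the baseline spec.  Whole-ganglion and per-nucleus
T1:T0 ratios then feed the nonparametric group statistics.

The statistical unit is the ganglion throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dyncontrast import (
    BAND_NAMES,
    DEFAULT_BANDS,
    AcquisitionParams,
    BandTriplet,
    DynamicImage,
    compute_dffoct,
    compute_static,
)
from .phantom import (
    PhantomSpec,
    TreatmentCondition,
    apply_treatment,
    build_scene,
    mannitol,
    rescue_dropouts,
    simulate_timestack,
    ttx,
    vehicle,
    veratridine,
)
from .quantify import (
    classify_by_area,
    measure_regions,
    segment_ganglia,
    segment_nuclei,
)
from .response import (
    TreatmentExperiment,
    compare_two_groups,
    dose_response,
    per_nucleus_response,
    ratio_percent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateResult",
    "small_experiment_spec",
    "run_replicate",
    "run_two_group_experiment",
    "run_dose_response_experiment",
    "run_figure_experiment",
]


def small_experiment_spec(seed: int = 0) -> PhantomSpec:
    """A compact phantom (128 × 128 µm, 2 ganglia) for treatment replicates."""
    from .phantom import GanglionGeometry

    return PhantomSpec(
        field_of_view=(128.0, 128.0),
        n_ganglia=2,
        ganglion_geometry=GanglionGeometry(
            semi_major_range=(20.0, 25.0), axis_ratio_range=(1.1, 1.4),
            margin=6.0,
        ),
        class_counts={"neuron": 5, "glia": 3},
        seed=seed,
    )


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for k in range(total - base * parts):
        out[k] += 1
    return out


def run_area_recovery(
    n_neuron: int = 219,
    n_glia: int = 125,
    seed: int = 0,
    *,
    n_phantoms: int = 8,
    dropout: dict[str, float] | None = None,
    acq: AcquisitionParams | None = None,
) -> dict:
    """Nuclear-area recovery experiment at the study's class Gaussians.

    The requested class populations (defaults: 219 neurons, 125 glia, the
    sizes of the study's morphometry sample) are split across ``n_phantoms``
    independent phantoms, each simulated, processed to a dynamic image,
    segmented and measured; detections are matched back to ground truth so
    each measured area carries its true class.  ``dropout`` defaults to the
    study's detection-dropout rates; pass ``{"neuron": 0, "glia": 0}`` to
    put the full populations on the images.

    Returns per-class measured-area summaries, the pooled measurement table,
    and the pooled per-class detection percentages.
    """
    from .phantom import GanglionGeometry

    if acq is None:
        acq = AcquisitionParams()
    neuron_counts = _split_count(n_neuron, n_phantoms)
    glia_counts = _split_count(n_glia, n_phantoms)
    rows = []
    detected = {"neuron": 0, "glia": 0}
    totals = {"neuron": 0, "glia": 0}
    for k in range(n_phantoms):
        spec = PhantomSpec(
            field_of_view=(288.0, 288.0),
            n_ganglia=4,
            ganglion_geometry=GanglionGeometry(semi_major_range=(32.0, 44.0)),
            class_counts={"neuron": neuron_counts[k], "glia": glia_counts[k]},
            detection_dropout=dropout if dropout is not None
            else {"neuron": 0.04, "glia": 0.22},
            seed=int(seed) * 1000 + k,
        )
        scene = build_scene(spec)
        stack = simulate_timestack(scene, spec, acq)
        dyn = compute_dffoct(stack, acq)
        static = compute_static(stack)
        ganglia = segment_ganglia(static, dyn)
        labels = segment_nuclei(dyn, ganglia)
        records = classify_by_area(measure_regions(labels, dyn))
        from .quantify import match_to_ground_truth

        det_table = match_to_ground_truth(records, scene)
        gt = {n.id: n for n in scene.nuclei}
        for cls in ("neuron", "glia"):
            row = det_table[det_table["class"] == cls].iloc[0]
            detected[cls] += int(row["detected"])
            totals[cls] += int(row["total"])
        for r in records:
            if r.matched_gt_id is None:
                continue
            info = gt[r.matched_gt_id]
            rows.append(
                {
                    "phantom": k,
                    "gt_id": info.id,
                    "gt_class": info.cls,
                    "gt_raster_area_um2": info.raster_area_um2,
                    "gt_analytic_area_um2": info.analytic_area_um2,
                    "measured_area_um2": r.area_um2,
                    "predicted_class": r.predicted_class,
                }
            )
    table = pd.DataFrame(rows)
    summary = {}
    for cls in ("neuron", "glia"):
        sub = table[table["gt_class"] == cls]
        areas = sub["measured_area_um2"].to_numpy()
        summary[cls] = {
            "n": int(len(areas)),
            "mean_area_um2": float(areas.mean()) if len(areas) else float("nan"),
            "sd_area_um2": float(areas.std(ddof=1)) if len(areas) > 1 else float("nan"),
            "frac_ge_65": float((areas >= 65.0).mean()) if len(areas) else float("nan"),
            "detected": detected[cls],
            "total": totals[cls],
        }
    return {"table": table, "summary": summary}


@dataclass
class ReplicateResult:
    """Everything one phantom replicate yields."""

    condition: str
    seed: int
    ganglion_ratios: pd.DataFrame  # whole-ganglion mask ratios, long format
    nucleus_ganglion_table: pd.DataFrame  # per_nucleus_response aggregate
    n_emergent: int
    dyn_t0: DynamicImage
    dyn_t1: DynamicImage
    dyn_t2: DynamicImage | None


def run_replicate(
    condition: TreatmentCondition,
    seed: int,
    *,
    spec: PhantomSpec | None = None,
    acq: AcquisitionParams | None = None,
    bands: BandTriplet = DEFAULT_BANDS,
    with_washout: bool = False,
) -> ReplicateResult:
    """Simulate one T0/T1(/T2) phantom replicate and quantify it."""
    if spec is None:
        spec = small_experiment_spec(seed)
    else:
        spec = dataclasses.replace(spec, seed=seed)
    if acq is None:
        acq = AcquisitionParams()

    scene = build_scene(spec)
    ss = lambda stream: np.random.default_rng(  # noqa: E731
        np.random.SeedSequence([int(seed), stream])
    )
    stack_t0 = simulate_timestack(scene, spec, acq, bands, rng=ss(1))

    treated_spec = apply_treatment(spec, condition)
    scene_t1 = scene
    if condition.dropout_rescue_prob > 0:
        scene_t1 = rescue_dropouts(scene, condition.dropout_rescue_prob, ss(4))
    stack_t1 = simulate_timestack(scene_t1, treated_spec, acq, bands, rng=ss(5))

    dyn_t0 = compute_dffoct(stack_t0, acq, bands)
    dyn_t1 = compute_dffoct(stack_t1, acq, bands)
    dyn_t2 = None
    if with_washout:
        stack_t2 = simulate_timestack(scene, spec, acq, bands, rng=ss(6))
        dyn_t2 = compute_dffoct(stack_t2, acq, bands)

    static_t0 = compute_static(stack_t0)
    ganglia = segment_ganglia(static_t0, dyn_t0)
    labels = segment_nuclei(dyn_t0, ganglia)
    records = classify_by_area(measure_regions(labels, dyn_t0))
    t1_labels = segment_nuclei(dyn_t1, ganglia)

    exp = TreatmentExperiment(
        condition=condition.name,
        dyn_t0=dyn_t0,
        dyn_t1=dyn_t1,
        dyn_t2=dyn_t2,
        ganglion_labels=ganglia,
        nucleus_labels=labels,
        records=records,
        t1_labels=t1_labels,
    )
    gang_table, _, n_emergent = per_nucleus_response(exp)

    rows = []
    for gid in np.unique(ganglia):
        if gid == 0:
            continue
        mask = ganglia == gid
        r1 = ratio_percent(dyn_t1, dyn_t0, mask)
        r2 = ratio_percent(dyn_t2, dyn_t0, mask) if dyn_t2 is not None else None
        for band in BAND_NAMES:
            rows.append(
                {
                    "condition": condition.name,
                    "seed": seed,
                    "ganglion_id": int(gid),
                    "band": band,
                    "ratio_t1_t0": r1[band],
                    "ratio_t2_t0": r2[band] if r2 is not None else None,
                }
            )
    return ReplicateResult(
        condition.name, seed, pd.DataFrame(rows), gang_table, n_emergent,
        dyn_t0, dyn_t1, dyn_t2,
    )


def _collect(
    condition: TreatmentCondition,
    seeds: Sequence[int],
    **kwargs,
) -> pd.DataFrame:
    frames = []
    for seed in seeds:
        rep = run_replicate(condition, seed, **kwargs)
        df = rep.ganglion_ratios.copy()
        df["n_emergent"] = rep.n_emergent
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_two_group_experiment(
    treated: TreatmentCondition,
    control: TreatmentCondition,
    seeds: Sequence[int],
    **kwargs,
) -> dict:
    """Treated vs vehicle whole-ganglion ratios + per-band Mann-Whitney."""
    df_t = _collect(treated, seeds, **kwargs)
    df_c = _collect(control, [s + 10_000 for s in seeds], **kwargs)
    table = pd.concat([df_t, df_c], ignore_index=True)
    stats = {}
    for band in BAND_NAMES:
        t_vals = df_t.loc[df_t["band"] == band, "ratio_t1_t0"].to_numpy()
        c_vals = df_c.loc[df_c["band"] == band, "ratio_t1_t0"].to_numpy()
        stats[band] = compare_two_groups(t_vals, c_vals)
        stats[band]["median_treated"] = float(np.median(t_vals))
        stats[band]["median_control"] = float(np.median(c_vals))
    return {
        "table": table,
        "stats": stats,
        "n_emergent_treated": int(df_t["n_emergent"].iloc[0]) if len(df_t) else 0,
    }


def run_dose_response_experiment(
    doses_mm: Sequence[float],
    seeds: Sequence[int],
    *,
    with_washout: bool = False,
    **kwargs,
) -> dict:
    """Mannitol dose series (0 = Krebs vehicle) with Kruskal-Wallis + Dunn."""
    tables = {}
    for i, dose in enumerate(doses_mm):
        cond = vehicle("Krebs") if dose == 0 else mannitol(dose)
        tables[f"{dose:g}"] = _collect(
            cond, [s + 1000 * i for s in seeds],
            with_washout=with_washout, **kwargs,
        )
    stats = {}
    for band in BAND_NAMES:
        groups = {
            key: df.loc[df["band"] == band, "ratio_t1_t0"].to_numpy()
            for key, df in tables.items()
        }
        stats[band] = dose_response(groups, control_key=f"{doses_mm[0]:g}")
    table = pd.concat(tables.values(), ignore_index=True)
    return {"table": table, "stats": stats}


def run_figure_experiment(
    figure: str,
    seed: int = 0,
    out_dir: Path | None = None,
    n_replicates: int = 3,
) -> dict:
    """Run the in-silico analogue of one pharmacology experiment.

    ``figure`` selects the design: "4" veratridine 75 µM vs DMSO vehicle,
    "5" TTX 1 µM vs Krebs vehicle, "6" mannitol 100/200/300 mM dose series
    with washout.  Magnitudes of the simulated effects are generator
    defaults, not published numbers; only the directions are anchored.
    """
    seeds = [seed + k for k in range(n_replicates)]
    if figure == "4":
        result = run_two_group_experiment(
            veratridine(), vehicle("DMSO"), seeds
        )
    elif figure == "5":
        result = run_two_group_experiment(ttx(), vehicle("Krebs"), seeds)
    elif figure == "6":
        result = run_dose_response_experiment(
            [0.0, 100.0, 200.0, 300.0], seeds, with_washout=True
        )
    else:
        raise ValueError(f"unknown experiment {figure!r}")
    summary = {
        "experiment": figure,
        "n_replicates": n_replicates,
        "stats": result["stats"],
    }
    result["summary"] = summary
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result["table"].to_csv(out_dir / f"experiment_{figure}_ratios.csv",
                               index=False)
        (out_dir / f"experiment_{figure}_stats.json").write_text(
            json.dumps(summary, indent=2, default=str)
        )
    return result
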