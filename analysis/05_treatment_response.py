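#!/usr/bin/env python
"""In-silico pharmacology: veratridine, TTX and mannitol dose-response.

Runs the three treatment experiments on the compact phantom (T0 baseline,
T1 after treatment, T2 washout for mannitol), computes whole-ganglion and
per-nucleus T1:T0 band-intensity ratios, and applies the study's
nonparametric statistics (Mann-Whitney for two-group designs,
Kruskal-Wallis + Dunn vs vehicle for the dose series).  Effect magnitudes
are generator defaults; only their directions are anchored to the source
experiments.
"""

from pathlib import Path

from dffoct.experiments import run_figure_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "response"
LABELS = {"4": "veratridine 75 µM vs DMSO",
          "5": "TTX 1 µM vs Krebs",
          "6": "mannitol 0/100/200/300 mM + washout"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for figure in ("4", "5", "6"):
        print(f"=== experiment {figure}: {LABELS[figure]} ===")
        result = run_figure_experiment(figure, seed=1, out_dir=OUT,
                                       n_replicates=2)
        for band, stats in result["stats"].items():
            if "median_treated" in stats:
                print(f"{band:>6}: treated {stats['median_treated']:.0f}% "
                      f"vs control {stats['median_control']:.0f}% "
                      f"(p = {stats['p']:.3f}, {stats['direction']})")
            else:
                med = stats["medians"]
                doses = " -> ".join(f"{med[k]:.0f}%" for k in med)
                print(f"{band:>6}: medians {doses} "
                      f"(KW p = {stats['p_omnibus']:.3f}, "
                      f"trend {stats['median_trend']})")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
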