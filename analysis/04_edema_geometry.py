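#!/usr/bin/env python
"""Edema-outline geometry: iso-distance null versus perturbed scenario.

On the default phantom, builds an edema mask that is exactly an iso-distance
region (the null hypothesis of threshold-like MR visibility over a monotone
density profile) and one whose outline is smoothly perturbed.  Compares the
inverse cumulative distributions of boundary distances and the
Hausdorff/ASSD threshold scans: the null gives a step ICDF and near-zero
scan minima at the generating threshold, the perturbed outline a continuous
ICDF and a Hausdorff minimum far above the ASSD minimum.  Writes curves and
a summary to results/edema/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import gliodensity as gd
from gliodensity.edema import boundary_distance_icdf, boundary_voxels, threshold_scan

OUT = Path(__file__).resolve().parent.parent / "results" / "edema"
SEED = 1
THRESHOLD_MM = 20.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    labels = gd.make_brain_phantom(seed=0)
    distance = gd.geodesic_distance(labels.core_mask, labels.white_mask, grid=labels.grid)
    domain = labels.white_mask | labels.core_mask

    summary = {}
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for mode, color in [("iso", "tab:red"), ("perturbed", "tab:blue")]:
        em = gd.make_edema_mask(distance, mode, THRESHOLD_MM, 10.0, 15.0, seed=SEED)
        boundary = boundary_voxels(em.mask, labels.grid, domain=domain)
        icdf = boundary_distance_icdf(boundary, distance)
        scan = threshold_scan(distance, em.mask, 1.0, None, 0.5, domain=domain)
        icdf["table"].to_csv(OUT / f"icdf_{mode}.csv", index=False)
        scan.curves.to_csv(OUT / f"scan_{mode}.csv", index=False)
        summary[mode] = {
            "boundary_voxels": len(boundary),
            "icdf_range_mm": icdf["range_mm"],
            "distance_at_5pct": icdf["quantiles"][0.05],
            "distance_at_1pct": icdf["quantiles"][0.01],
            "best_t_hausdorff_mm": scan.best_t_hausdorff,
            "best_t_assd_mm": scan.best_t_assd,
            "min_hausdorff_mm": scan.min_hausdorff,
            "min_assd_mm": scan.min_assd,
        }
        ax1.step(icdf["table"]["x_mm"], icdf["table"]["fraction"], color=color, label=mode)
        ax2.plot(scan.curves["t_mm"], scan.curves["hausdorff_mm"], color=color,
                 label=f"{mode} Hausdorff")
        ax2.plot(scan.curves["t_mm"], scan.curves["assd_mm"], color=color, ls="--",
                 label=f"{mode} ASSD")
        print(f"{mode:9s}: ICDF range {icdf['range_mm']:.2f} mm, "
              f"scan minima H={scan.min_hausdorff:.2f} mm at t={scan.best_t_hausdorff:.1f}, "
              f"ASSD={scan.min_assd:.2f} mm at t={scan.best_t_assd:.1f}")

    ax1.set_xlabel("geodesic distance x (mm)")
    ax1.set_ylabel("fraction of boundary voxels with d >= x")
    ax1.axvline(THRESHOLD_MM, color="gray", lw=0.8)
    ax1.legend()
    ax2.set_xlabel("distance threshold t (mm)")
    ax2.set_ylabel("surface distance to edema outline (mm)")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "icdf_and_scan.png", dpi=150)

    (OUT / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    ratio = summary["perturbed"]["min_hausdorff_mm"] / summary["perturbed"]["min_assd_mm"]
    print(f"perturbed outline: Hausdorff minimum is {ratio:.1f}x the ASSD minimum — "
          f"the outline is not an iso-distance contour")
    print(f"curves, figure and summary written to {OUT}")


if __name__ == "__main__":
    main()
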