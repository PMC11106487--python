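#!/usr/bin/env python
"""Generate the synthetic study conditions for the downstream analyses.

Emulates the three experiment families on one polarized-epithelium-like
cell model:

* localization (pc-STORM-type) conditions in 4x4 um ROIs: a clustered
  control at the 67-nm ground-truth domain diameter, an actin-perturbed
  condition with unchanged clustering (the epithelial phenotype), a
  calcium-chelated condition with randomized molecules, and an
  isolated-molecule reference used to estimate the localization error;
* N&B image time series at molecular brightness epsilon = B - 1 for the
  control (B = 1.21), fibroblast + actin-depolymerization (B = 1.15) and
  Golgi + calcium-chelation (B = 1.06) conditions;
* time-gated (5 x 2 ns) FLIM stacks for donor-only and donor+acceptor
  populations, the latter with a FRET subpopulation.

Raw inputs land under scratch/synth/ (large, regenerable); manifests for
the downstream scripts are written next to them.
"""

import argparse
from pathlib import Path

import numpy as np
import yaml

from nanodomain import (
    BlinkModel,
    ClusterGroundTruth,
    DecaySpec,
    RoiGeometry,
    simulate_gated_stack,
    simulate_localizations_clustered,
    simulate_localizations_random,
    simulate_nandb_stack,
)
from nanodomain import io as nio

N_ROIS = 12
N_CELLS = 8

STORM_CONDITIONS = {
    # name -> (clustered?, diameter_nm)
    "control": (True, 67.0),
    "latrunculin": (True, 67.0),
    "egta": (False, None),
    "reference_isolated": (True, None),  # handled as CSR below
}
NANDB_EPSILON = {"control": 0.21, "latrunculin_cho": 0.15, "egta_golgi": 0.06}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/synth"))
    args = ap.parse_args()
    rng_seeds = iter(
        int(s % 2**31)
        for s in np.random.SeedSequence(args.seed).generate_state(4096, dtype=np.uint32)
    )
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    roi = RoiGeometry(4000.0, 4000.0)
    blink = BlinkModel(mean_localizations=3.0, sigma_s_nm=20.0)
    storm_manifest = {"conditions": {}, "compare": [["control", "latrunculin"]]}
    for name, (clustered, diameter) in STORM_CONDITIONS.items():
        files = []
        for i in range(N_ROIS):
            seed = next(rng_seeds)
            if clustered and diameter is not None:
                truth = ClusterGroundTruth(
                    xi_nm=diameter / 2.0, amplitude=5.0, density_per_um2=600.0
                )
                sim = simulate_localizations_clustered(roi, truth, blink, seed=seed)
            else:
                sim = simulate_localizations_random(roi, 600.0, blink, seed=seed)
            path = out / f"storm_{name}_{i:02d}.csv"
            nio.write_localizations(sim.table, path)
            nio.write_ground_truth(sim.molecules_xy_nm,
                                   path.with_suffix(".ground_truth.csv"))
            files.append(str(path))
        storm_manifest["conditions"][name] = files
        print(f"storm/{name}: {N_ROIS} ROIs, "
              f"~{len(sim.table) / roi.area_um2:.0f} localizations/um^2")
    (out / "storm_manifest.yaml").write_text(yaml.safe_dump(storm_manifest))

    nandb_manifest = {"conditions": {},
                      "compare": [["control", "latrunculin_cho"],
                                  ["control", "egta_golgi"]]}
    for name, eps in NANDB_EPSILON.items():
        files = []
        for i in range(N_CELLS):
            stack = simulate_nandb_stack(
                n_frames=50, shape=(64, 256), mean_clusters_per_pixel=2.0,
                epsilon=eps, seed=next(rng_seeds),
            )
            path = out / f"nandb_{name}_{i:02d}.tif"
            nio.write_stack(stack, path, meta={"epsilon": eps})
            files.append(str(path))
        nandb_manifest["conditions"][name] = files
        print(f"nandb/{name}: {N_CELLS} cells at epsilon={eps}")
    (out / "nandb_manifest.yaml").write_text(yaml.safe_dump(nandb_manifest))

    # donor gated mean ~2.48 ns with 5 gates corresponds to tau ~2.55 ns
    donor = DecaySpec((2.554,), (1.0,), n_gates=5)
    donor_acceptor = DecaySpec((2.554, 1.0), (0.941, 0.059), n_gates=5)
    flim_manifest = {"conditions": {},
                     "compare": [["donor_only", "donor_plus_acceptor"]]}
    for name, decay in (("donor_only", donor),
                        ("donor_plus_acceptor", donor_acceptor)):
        files = []
        for i in range(35):
            gs = simulate_gated_stack(decay, shape=(32, 32),
                                      photons_per_pixel=1.0e4,
                                      seed=next(rng_seeds))
            path = out / f"flim_{name}_{i:02d}.tif"
            nio.write_gated_stack(gs, path)
            files.append(str(path))
        flim_manifest["conditions"][name] = files
        print(f"flim/{name}: 35 cells, {decay.n_gates} gates")
    (out / "flim_manifest.yaml").write_text(yaml.safe_dump(flim_manifest))
    print(f"all synthetic inputs under {out}")


if __name__ == "__main__":
    main()
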