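#!/usr/bin/env python
"""Pair-correlation analysis of the synthetic localization conditions.

Estimates the localization error sigma_s from the isolated-molecule
reference, then classifies each condition as clustered or random
(Kolmogorov-Smirnov on the two models' fit-error distributions) and
compares cluster-size distributions between control and the
actin-perturbed condition with a rank-sum test.  Expected outcome: control
and actin-perturbed both clustered at ~67 nm with a non-significant size
shift; the calcium-chelated condition random.
"""

import argparse
from pathlib import Path

import numpy as np
import yaml

from nanodomain import (
    ConditionManifest,
    RunConfig,
    compute_pair_correlation,
    fit_random_model,
    run_pcstorm_pipeline,
)
from nanodomain import io as nio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--synth", type=Path, default=Path("scratch/synth"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    manifest_data = yaml.safe_load((args.synth / "storm_manifest.yaml").read_text())
    reference = manifest_data["conditions"].pop("reference_isolated")
    manifest = ConditionManifest(
        conditions=manifest_data["conditions"],
        compare=[tuple(p) for p in manifest_data.get("compare", [])],
    )

    sigmas = [
        fit_random_model(
            compute_pair_correlation(nio.read_localizations(p))
        ).sigma_s_nm
        for p in reference
    ]
    pooled = float(np.mean(sigmas))
    print(f"sigma_s from isolated-molecule reference: {pooled:.1f} nm "
          f"(n={len(sigmas)} ROIs)")

    config = RunConfig.from_mapping({
        "seed": 1,
        "output_dir": str(args.outdir),
        "pcstorm": {"sigma_mode": "pooled", "pooled_sigma_nm": pooled},
    })
    report = run_pcstorm_pipeline(config, manifest)
    for cond, res in report["conditions"].items():
        line = (f"{cond}: {res['verdict']} (KS p = {res['ks_p_value']:.3g}, "
                f"{res['mean_density_per_um2']:.0f} localizations/um^2)")
        if res["verdict"] == "clustered":
            line += (f", diameter {res['diameter_nm_mean']:.1f} nm "
                     f"(median {res['diameter_nm_median']:.1f})")
        print(line)
    for comp in report["comparisons"]:
        if comp["p_value"] is not None:
            print(f"cluster sizes {comp['a']} vs {comp['b']}: "
                  f"rank-sum p = {comp['p_value']:.3g}")
    print(f"tables under {args.outdir}/ (pcstorm_report.json, pcstorm_fits.csv)")


if __name__ == "__main__":
    main()
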