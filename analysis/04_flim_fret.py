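#!/usr/bin/env python
"""Time-gated FLIM analysis of the synthetic donor populations.

Smooths each gated stack with the 3x3 mask, computes per-pixel gated mean
lifetimes, averages per cell, and tests donor-only vs donor+acceptor with
a two-tailed t-test.  Expected outcome: donor gated mean ~2.48 ns dropping
to ~2.41 ns with the acceptor present — a significant decrease, i.e. the
two proteins are within FRET distance.
"""

import argparse
from pathlib import Path

import yaml

from nanodomain import ConditionManifest, RunConfig, run_flim_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--synth", type=Path, default=Path("scratch/synth"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = yaml.safe_load((args.synth / "flim_manifest.yaml").read_text())
    manifest = ConditionManifest(
        conditions=data["conditions"],
        compare=[tuple(p) for p in data.get("compare", [])],
    )
    config = RunConfig.from_mapping({"seed": 1, "output_dir": str(args.outdir)})
    report = run_flim_pipeline(config, manifest)
    for cond, res in report["conditions"].items():
        print(f"{cond}: tau = {res['mean_tau_ns']:.3f} +/- {res['sd_tau_ns']:.3f} ns "
              f"({res['n_cells']} cells)")
    for comp in report["comparisons"]:
        verdict = "FRET (donor lifetime decreased)" if comp["fret"] else "no FRET"
        print(f"{comp['donor_only']} vs {comp['donor_plus_acceptor']}: "
              f"t = {comp['t_statistic']:.2f}, p = {comp['p_value']:.3g} -> {verdict}")
    print(f"tables under {args.outdir}/ (flim_report.json)")


if __name__ == "__main__":
    main()
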