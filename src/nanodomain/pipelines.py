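"""Condition-level pipelines tying the analysis stages together.

Each pipeline consumes a :class:`~nanodomain.config.RunConfig` and a
:class:`~nanodomain.config.ConditionManifest`, processes every input of
every condition, isolates per-input failures (the run continues and the
failure is reported), and writes JSON reports plus CSV tables stamped with
the configuration hash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import clusterfit, flim, io as nio, nandb, paircorr
from .config import ConditionManifest, RunConfig, config_hash
from .exceptions import ParameterError

__all__ = ["run_pcstorm_pipeline", "run_nandb_pipeline", "run_flim_pipeline"]

log = logging.getLogger(__name__)


def _prepare_outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_report(report: dict, config: RunConfig, path: Path) -> None:
    report = {"config_hash": config_hash(config), **report}
    path.write_text(json.dumps(report, indent=1, default=_jsonable))
    log.info("wrote %s", path)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pcstorm_pipeline(
    config: RunConfig, manifest: ConditionManifest
) -> Dict[str, dict]:
    """Curves -> model fits -> classification per condition, plus
    cross-condition cluster-size comparisons for clustered pairs."""
    out = _prepare_outdir(config)
    p = config.pcstorm
    results: Dict[str, dict] = {}
    rows = []
    for cond, inputs in manifest.conditions.items():
        curves, failures = [], []
        for item in inputs:
            try:
                locs = nio.read_localizations(item)
                curves.append(
                    paircorr.compute_pair_correlation(
                        locs, bin_nm=p.bin_nm, r_max_nm=p.r_max_nm, grid_nm=p.grid_nm
                    )
                )
            except Exception as exc:
                log.warning("condition %s: input %s failed: %s", cond, item, exc)
                failures.append({"input": str(item), "error": str(exc)})
        if len(curves) < 8:
            raise ParameterError(
                f"condition {cond!r}: need >= 8 usable ROIs, got {len(curves)}"
            )
        cls = clusterfit.classify_condition(
            curves,
            fit_range=(p.fit_min_nm, p.fit_max_nm),
            sigma_mode=p.sigma_mode,  # type: ignore[arg-type]
            pooled_sigma_nm=p.pooled_sigma_nm,
            alpha=p.ks_alpha,
        )
        for i, (rf, cf) in enumerate(zip(cls.random_fits, cls.clustered_fits)):
            rows.append({
                "condition": cond, "roi": i,
                "sigma_s_nm": rf.sigma_s_nm, "mse_random": rf.mse,
                "amplitude": cf.amplitude, "xi_nm": cf.xi_nm,
                "diameter_nm": cf.diameter_nm, "mse_clustered": cf.mse,
            })
        results[cond] = {
            "n_rois": len(curves),
            "failures": failures,
            "verdict": cls.verdict,
            "ks_statistic": cls.ks_statistic,
            "ks_p_value": cls.p_value,
            "mean_density_per_um2": float(
                np.mean([c.density_per_um2 for c in curves])
            ),
            "xi_nm": cls.xi_nm.tolist(),
            "diameter_nm_mean": float(np.mean(cls.diameters_nm))
            if cls.xi_nm.size else None,
            "diameter_nm_median": float(np.median(cls.diameters_nm))
            if cls.xi_nm.size else None,
        }
    comparisons = []
    for a, b in manifest.compare:
        if results[a]["verdict"] == "clustered" and results[b]["verdict"] == "clustered":
            stat, pval = clusterfit.compare_cluster_sizes(
                np.array(results[a]["xi_nm"]), np.array(results[b]["xi_nm"])
            )
            comparisons.append({"a": a, "b": b, "test": "rank-sum",
                                "statistic": stat, "p_value": pval})
        else:
            comparisons.append({
                "a": a, "b": b, "test": "rank-sum", "statistic": None,
                "p_value": None,
                "note": "size comparison requires both conditions clustered",
            })
    pd.DataFrame(rows).to_csv(out / "pcstorm_fits.csv", index=False)
    report = {"parameters": asdict(p), "conditions": results,
              "comparisons": comparisons}
    _write_report(report, config, out / "pcstorm_report.json")
    return report


def run_nandb_pipeline(
    config: RunConfig, manifest: ConditionManifest
) -> Dict[str, dict]:
    """Detrend -> brightness maps -> oligomer partition -> condition stats."""
    out = _prepare_outdir(config)
    p = config.nandb
    if p.photon_counting:
        calib = nandb.PHOTON_COUNTING_CALIBRATION
    else:
        if p.gain_s == 1.0 and p.offset == 0.0 and p.sigma0 == 0.0:
            raise ParameterError(
                "analog mode requires a detector calibration (gain_s/offset/"
                "sigma0) or photon_counting: true"
            )
        calib = nandb.DetectorCalibration(p.gain_s, p.offset, p.sigma0)
    curve = None
    if p.calibration_b is not None:
        curve = nandb.oligomer_calibration_curve(*p.calibration_b)

    results: Dict[str, dict] = {}
    per_cell: Dict[str, list] = {}
    rows = []
    for cond, inputs in manifest.conditions.items():
        cell_b, pct_list, failures = [], [], []
        for item in inputs:
            try:
                stack, _ = nio.read_stack(item)
                bm = nandb.brightness_map(stack, calib, detrend_window=p.detrend_window)
                cell_b.append(bm.mean_b())
                if curve is not None:
                    pct_list.append(nandb.partition_brightness(bm, curve))
            except Exception as exc:
                log.warning("condition %s: input %s failed: %s", cond, item, exc)
                failures.append({"input": str(item), "error": str(exc)})
        if not cell_b:
            raise ParameterError(f"condition {cond!r}: no usable inputs")
        per_cell[cond] = cell_b
        entry = {
            "n_cells": len(cell_b),
            "failures": failures,
            "mean_b": float(np.mean(cell_b)),
            "sd_b": float(np.std(cell_b, ddof=1)) if len(cell_b) > 1 else 0.0,
        }
        if pct_list:
            mean_pct = np.mean(np.vstack(pct_list), axis=0)
            entry["class_percent"] = mean_pct.tolist()
            for n_mer, pc_val in enumerate(mean_pct, start=1):
                rows.append({"condition": cond, "n_mer": n_mer, "percent": pc_val})
        results[cond] = entry
    comparisons = []
    for a, b in manifest.compare:
        t, pval = stats.ttest_ind(per_cell[a], per_cell[b])
        comparisons.append({"a": a, "b": b, "test": "t-test (two-tailed)",
                            "statistic": float(t), "p_value": float(pval)})
    if rows:
        pd.DataFrame(rows).to_csv(out / "nandb_classes.csv", index=False)
    report = {"parameters": asdict(p), "conditions": results,
              "comparisons": comparisons}
    _write_report(report, config, out / "nandb_report.json")
    return report


def run_flim_pipeline(
    config: RunConfig, manifest: ConditionManifest
) -> Dict[str, dict]:
    """Smoothing -> lifetime maps -> per-cell means -> FRET comparisons."""
    out = _prepare_outdir(config)
    p = config.flim
    results: Dict[str, dict] = {}
    per_cell: Dict[str, list] = {}
    for cond, inputs in manifest.conditions.items():
        taus, failures = [], []
        n_gates_seen = set()
        for item in inputs:
            try:
                gs = nio.read_gated_stack(item)
                n_gates_seen.add(gs.n_gates)
                lt = flim.mean_lifetime_map(gs, intensity_floor=p.intensity_floor)
                taus.append(lt.cell_mean_ns(weighting=p.weighting))  # type: ignore[arg-type]
            except Exception as exc:
                log.warning("condition %s: input %s failed: %s", cond, item, exc)
                failures.append({"input": str(item), "error": str(exc)})
        if len(n_gates_seen) > 1:
            raise ParameterError(
                f"condition {cond!r}: gate-count mismatch across inputs: "
                f"{sorted(n_gates_seen)}"
            )
        if not taus:
            raise ParameterError(f"condition {cond!r}: no usable inputs")
        per_cell[cond] = taus
        results[cond] = {
            "n_cells": len(taus),
            "failures": failures,
            "mean_tau_ns": float(np.mean(taus)),
            "sd_tau_ns": float(np.std(taus, ddof=1)) if len(taus) > 1 else 0.0,
        }
    comparisons = []
    for donor, da in manifest.compare:
        cmp_res = flim.fret_compare(per_cell[donor], per_cell[da], alpha=p.alpha)
        comparisons.append({"donor_only": donor, "donor_plus_acceptor": da,
                            **asdict(cmp_res)})
    report = {"parameters": asdict(p), "conditions": results,
              "comparisons": comparisons}
    _write_report(report, config, out / "flim_report.json")
    return report
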