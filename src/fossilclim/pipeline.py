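"""End-to-end orchestration and abrupt-event magnitude statistics.

:func:`run_pipeline` executes the full inference chain on a single YAML
config: percentages -> zonation -> ensemble reconstruction -> analogue report
-> significance test -> age-depth model -> event magnitudes, writing every
stage's output plus a manifest (config hash, seed, library versions) into a
run directory. Runs are deterministic: identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analogue import analogue_distances, analogue_geography, analogue_threshold
from .calibration import EnsembleReconstruction, reconstruct_ensemble
from .chronology import TiePoint, fit_psequence, uncertainty_profile
from .io import (AssemblageTable, percentages, read_assemblage, read_climate,
                 write_assemblage, write_climate)
from .significance import random_tf_test
from .synthetic import (ClimateTrajectory, TrajectoryParams, AbruptEvent,
                        default_scenario, eemian_like_trajectory)
from .zonation import fit_mrt, zone_table

logger = logging.getLogger("fossilclim")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage, err):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class EventReport:
    """Cooling magnitude of one abrupt event across the method ensemble.

    Per method, ``delta_t = mean(estimate over reference window) -
    mean(estimate over event window)`` (positive = cooling during the event,
    whichever window comes first stratigraphically).
    """

    name: str
    event_window: tuple[float, float]
    reference_window: tuple[float, float]
    per_method: dict[str, float]
    mean_delta_t: float
    range: tuple[float, float]
    n_event_samples: int
    n_reference_samples: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "event_window_m": list(self.event_window),
            "reference_window_m": list(self.reference_window),
            "per_method_delta_t_c": self.per_method,
            "mean_delta_t_c": self.mean_delta_t,
            "range_delta_t_c": list(self.range),
            "n_event_samples": self.n_event_samples,
            "n_reference_samples": self.n_reference_samples,
        }


def _window_mask(depths, window):
    lo, hi = sorted(window)
    return (depths >= lo) & (depths <= hi)


def event_magnitude(ensemble: EnsembleReconstruction, event_window,
                    reference_window, name: str = "event") -> EventReport:
    """Per-method and mean event cooling from an ensemble reconstruction."""
    depths = ensemble.depths
    ev = _window_mask(depths, event_window)
    rf = _window_mask(depths, reference_window)
    if not ev.any():
        raise ValueError(f"event window {event_window} contains no samples")
    if not rf.any():
        raise ValueError(f"reference window {reference_window} contains no samples")
    if (ev & rf).any():
        raise ValueError("event and reference windows overlap")
    per_method = {
        m: float(rec.estimates[rf].mean() - rec.estimates[ev].mean())
        for m, rec in ensemble.members.items()
    }
    vals = np.array(list(per_method.values()))
    return EventReport(
        name=name,
        event_window=tuple(sorted(event_window)),
        reference_window=tuple(sorted(reference_window)),
        per_method=per_method,
        mean_delta_t=float(vals.mean()),
        range=(float(vals.min()), float(vals.max())),
        n_event_samples=int(ev.sum()),
        n_reference_samples=int(rf.sum()),
    )


def true_event_magnitude(trajectory: ClimateTrajectory, event_window,
                         reference_window, var: str = "t_jul") -> float:
    """Truth-trajectory window contrast matching :func:`event_magnitude`."""
    vals = trajectory.t_jul if var == "t_jul" else trajectory.t_jan
    ev = _window_mask(trajectory.depths, event_window)
    rf = _window_mask(trajectory.depths, reference_window)
    if not ev.any() or not rf.any():
        raise ValueError("window contains no trajectory samples")
    return float(vals[rf].mean() - vals[ev].mean())


def default_event_windows(trajectory: ClimateTrajectory,
                          reference_width: float = 0.5) -> list[dict]:
    """Event/reference windows for a synthetic trajectory: each injected
    event window paired with the adjacent deeper (preceding) interval."""
    out = []
    for ev in trajectory.events:
        out.append(
            {
                "name": ev.name,
                "event_window": [ev.depth_lo, ev.depth_hi],
                "reference_window": [ev.depth_hi, ev.depth_hi + reference_width],
            }
        )
    return out


# ---------------------------------------------------------------------------
# Config-driven run
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _build_trajectory(cfg: dict | None) -> TrajectoryParams:
    cfg = dict(cfg or {})
    if "events" in cfg:
        cfg["events"] = tuple(
            AbruptEvent(e["name"], float(e["depth_lo"]), float(e["depth_hi"]),
                        float(e["delta_t_jul"]))
            for e in cfg["events"]
        )
    return TrajectoryParams(**cfg)


def _load_inputs(cfg: dict, seed: int, out: Path):
    """Return (calibration, climate, fossil, trajectory-or-None)."""
    if "synthetic" in cfg:
        s = dict(cfg["synthetic"])
        params = _build_trajectory(s.pop("trajectory", None))
        scen = default_scenario(seed=seed, trajectory_params=params, **s)
        write_assemblage(scen.calibration, out / "calibration_counts.csv")
        write_climate(scen.climate, out / "calibration_climate.csv")
        write_assemblage(scen.fossil, out / "fossil_counts.csv")
        scen.trajectory.truth_frame().to_csv(out / "truth.csv", index=False)
        return scen.calibration, scen.climate, scen.fossil, scen.trajectory
    inputs = cfg["inputs"]
    for key in ("calibration_counts", "calibration_climate", "fossil_counts"):
        if key not in inputs:
            raise ValueError(f"config inputs missing {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file for {key!r} not found: {inputs[key]}")
    calibration = read_assemblage(inputs["calibration_counts"],
                                  inputs.get("calibration_groups"))
    climate = read_climate(inputs["calibration_climate"])
    fossil = read_assemblage(inputs["fossil_counts"], inputs.get("fossil_groups"))
    return calibration, climate, fossil, None


def run_pipeline(config, out_dir=None) -> Path:
    """Run the full chain described by ``config``; returns the run directory.

    Stage failures raise :class:`PipelineError` naming the stage; outputs of
    completed stages are kept.
    """
    cfg = _load_config(config)
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg.get("output_dir", "fossilclim_run"))
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_stages(cfg, seed, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(cfg, seed, out) -> Path:
    stage = "inputs"
    try:
        calibration, climate, fossil, trajectory = _load_inputs(cfg, seed, out)
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "percentages"
    try:
        fossil_pct = percentages(fossil) if fossil.unit != "percent" else fossil
        write_assemblage(fossil_pct, out / "fossil_percent.csv")
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "zonation"
    try:
        zcfg = cfg.get("zonation", {})
        tree = fit_mrt(
            fossil_pct,
            max_zones=zcfg.get("max_zones", 10),
            cv_folds=zcfg.get("cv_folds", 10),
            n_cv_reps=zcfg.get("n_cv_reps", 50),
            seed=seed,
        )
        zones = zone_table(tree, fossil_pct)
        zones.to_csv(out / "zones.csv")
        tree.cv_table_.to_csv(out / "zonation_cv.csv", index=False)
        logger.info("zonation: %d zones, boundaries %s", tree.size_, tree.split_depths_)
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "reconstruction"
    ensembles = {}
    try:
        rcfg = cfg.get("reconstruction", {})
        for var in cfg.get("climate_vars", ["t_jul", "t_jan"]):
            ens = reconstruct_ensemble(
                calibration, climate, fossil,
                climate_var=var,
                methods=tuple(rcfg.get("methods", ("WA", "WAPLS", "MAT", "MLRC", "BRT", "RF"))),
                seed=seed,
                compute_cv=rcfg.get("compute_cv", True),
                loess_span=rcfg.get("loess_span", 0.03),
            )
            ensembles[var] = ens
            ens.to_frame().to_csv(out / f"reconstruction_{var}.csv", index=False)
            if ens.cv_stats:
                pd.DataFrame(
                    {
                        m: {"rmsep": s.rmsep, "r2": s.r2, "max_bias": s.max_bias}
                        for m, s in ens.cv_stats.items()
                    }
                ).T.to_csv(out / f"cv_stats_{var}.csv")
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "analogue"
    try:
        acfg = cfg.get("analogue", {})
        report = analogue_distances(fossil, calibration,
                                    n_neighbors=acfg.get("n_neighbors", 5))
        ref = acfg.get("reference_distances")
        if ref is None:
            # no reference core supplied: use the calibration set's own
            # nearest-neighbour distances as the reference population
            self_report = analogue_distances(calibration, calibration, n_neighbors=2)
            ref = self_report.neighbor_distances[:, 1]
            logger.info("analogue: default reference = calibration self-distances")
        analogue_threshold(report, ref)
        frame = report.to_frame()
        if climate.has_coordinates:
            geo = analogue_geography(fossil, calibration, climate,
                                     n=acfg.get("n_neighbors", 5))
            frame[["analogue_lat", "analogue_lon"]] = geo[["lat", "lon"]].to_numpy()
        frame.to_csv(out / "analogue_report.csv")
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "significance"
    try:
        scfg = cfg.get("significance", {})
        sig_out = {}
        for var in scfg.get("variables", ["t_jul"]):
            res = random_tf_test(
                calibration, climate, fossil,
                method=scfg.get("method", "MAT"),
                climate_var=var,
                n_perm=scfg.get("n_perm", 99),
                subset=tuple(scfg["subset"]) if "subset" in scfg else None,
                seed=seed,
            )
            sig_out[var] = {
                "p": res.p, "ve_obs": res.ve_obs, "n_perm": res.n_perm,
                "method": res.method,
                "null_quantiles": {str(k): v for k, v in res.null_quantiles().items()},
            }
        with open(out / "significance.json", "w", encoding="utf-8") as fh:
            json.dump(sig_out, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "chronology"
    try:
        ccfg = cfg.get("chronology")
        if ccfg:
            ties = [
                TiePoint(float(t["depth_m"]), float(t["age_ka"]),
                         float(t["age_2sigma_ka"]))
                for t in ccfg["tie_points"]
            ]
            step = ccfg.get("grid_step_m", 0.01)
            lo = min(t.depth_m for t in ties)
            hi = max(t.depth_m for t in ties)
            grid = np.arange(lo, hi + step / 2, step)
            posterior = fit_psequence(
                ties, grid,
                k_rate=ccfg.get("k_rate", 1.0),
                n_draws=ccfg.get("n_draws", 1000),
                seed=seed,
            )
            posterior.summary().to_csv(out / "age_model.csv", index=False)
            uncertainty_profile(posterior).to_csv(out / "age_uncertainty.csv",
                                                  index=False)
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "events"
    try:
        events_cfg = cfg.get("events")
        if events_cfg is None and trajectory is not None:
            events_cfg = default_event_windows(trajectory)
            logger.info("events: windows derived from injected truth events")
        reports = []
        if events_cfg:
            ens = ensembles.get("t_jul") or next(iter(ensembles.values()))
            for e in events_cfg:
                rep = event_magnitude(ens, e["event_window"], e["reference_window"],
                                      name=e.get("name", "event"))
                d = rep.to_dict()
                if trajectory is not None:
                    d["true_delta_t_c"] = true_event_magnitude(
                        trajectory, e["event_window"], e["reference_window"]
                    )
                reports.append(d)
        with open(out / "events.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise PipelineError(stage, err) from err

    manifest = {
        "fossilclim_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
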