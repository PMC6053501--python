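"""End-to-end orchestration: one config in, a table bundle out.

A run config names one trajectory per solvent, a region map, bulk solvent
properties, and the numerical knobs of every stage (shell cutoffs, block
count, MSD fit window, MSM settings).  ``run_pipeline`` executes shells ->
solvent dynamics -> descriptors -> flexibility -> correlations (-> MSM)
and writes CSV/JSON tables plus a manifest with seeds and a config hash.
All numeric outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import correlation, dynamics, flexibility, shells, viscosity
from .io import RegionSpec, Trajectory, load_region_map, read_system, write_table

log = logging.getLogger("solvshell.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``runs`` maps solvent name to a dict with either ``trajectory`` (an
    in-memory :class:`Trajectory`) or ``topology``/``trajectory_path``
    files, optional bulk properties (``eta_exp``, ``D_exp``, ``D_model``
    — viscosity mPa·s, diffusion on the 1e-5 cm^2/s scale), an optional
    ``cutoff_nm`` and optional ``site_rules``.
    """

    runs: dict[str, dict[str, Any]]
    regions: dict[str, RegionSpec]
    outdir: Path
    block_count: int = 4
    fit_window: tuple[float, float] = (2.0, 10.0)
    origins_stride: float = 1.0
    rmsf_variants: tuple[str, ...] = ("all_atom",)
    water: str = "water"
    msm: dict[str, Any] | None = None
    seed: int = 7

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        regions = load_region_map(cfg["regions"])
        runs = dict(cfg["runs"])
        for name, run in runs.items():
            if "trajectory" not in run:
                for key in ("topology",):
                    if key not in run:
                        raise ValueError(
                            f"run {name!r}: missing {key!r} (or an in-memory "
                            "'trajectory')"
                        )
                    if not Path(run[key]).exists():
                        raise FileNotFoundError(run[key])
            rules = dict(shells.SITE_RULES) | dict(run.get("site_rules", {}))
            run["_rules"] = rules
        return cls(
            runs=runs,
            regions=regions,
            outdir=Path(cfg.get("outdir", "solvshell_out")),
            block_count=int(cfg.get("block_count", 4)),
            fit_window=tuple(cfg.get("fit_window", (2.0, 10.0))),
            origins_stride=float(cfg.get("origins_stride", 1.0)),
            rmsf_variants=tuple(cfg.get("rmsf_variants", ("all_atom",))),
            water=cfg.get("water", "water"),
            msm=cfg.get("msm"),
            seed=int(cfg.get("seed", 7)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _load_run_traj(run: dict[str, Any]) -> Trajectory:
    if "trajectory" in run and isinstance(run["trajectory"], Trajectory):
        return run["trajectory"]
    return read_system(
        run["topology"], run.get("trajectory_path"),
        classification_rules=run.get("classification_rules"),
        dt=run.get("dt"),
    )


def _validate_site_rules(name: str, run: dict[str, Any],
                         traj: Trajectory) -> None:
    solvent_resnames = {
        a.resname for a in traj.atoms if a.mol_class == "solvent"
    }
    missing = solvent_resnames - set(run["_rules"])
    if missing:
        raise ValueError(
            f"run {name!r}: no solvent reference-site rule for resname(s) "
            f"{sorted(missing)}"
        )


def _blocks(n_frames: int, k: int) -> list[slice]:
    edges = np.linspace(0, n_frames, k + 1).astype(int)
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])
            if b - a >= 2]


def _block_traj(traj: Trajectory, sl: slice) -> Trajectory:
    return Trajectory(
        atoms=traj.atoms, coords=traj.coords[sl], box=traj.box[sl],
        dt=traj.dt, origin_time=traj.origin_time + traj.dt * (sl.start or 0),
    )


def _dynamics_rows(
    cfg: RunConfig, name: str, traj: Trajectory, run: dict[str, Any]
) -> list[dict[str, Any]]:
    rows = []
    for rname, region in cfg.regions.items():
        cutoff = region.cutoff_nm or run.get("cutoff_nm")
        if cutoff is None and name.lower() in shells.DEFAULT_CUTOFFS_NM:
            cutoff = shells.default_cutoff(
                name, interior=(region.exposure == "Int")
            )
        if cutoff is None:
            raise ValueError(
                f"no shell cutoff for region {rname!r} in run {name!r}"
            )
        tc, th, dl = [], [], []
        lower_bound = False
        for sl in _blocks(traj.n_frames, cfg.block_count):
            bt = _block_traj(traj, sl)
            shell = shells.shell_membership(
                bt, region, cutoff, site_rules=run["_rules"]
            )
            _, tau_corr, tau_hist = dynamics.survival_residence(shell)
            lower_bound |= tau_corr.lower_bound or tau_hist.lower_bound
            tc.append(tau_corr.value)
            th.append(tau_hist.value)
            d = dynamics.diffusion_coefficient(
                bt, members_at_origin=shell, fit_window=cfg.fit_window,
                origins_stride=cfg.origins_stride, site_rules=run["_rules"],
            )
            dl.append(d.D_report)
        tcm, tcc = dynamics.block_ci(tc)
        thm, thc = dynamics.block_ci(th)
        dm, dc = dynamics.block_ci(dl)
        rows.append({
            "solvent": name, "region": rname, "cutoff_nm": cutoff,
            "tau_res_corr_ps": tcm, "tau_res_corr_ci": tcc,
            "tau_res_hist_ps": thm, "tau_res_hist_ci": thc,
            "tau_res_lower_bound": bool(lower_bound),
            "D_local_1e5cm2s": dm, "D_local_ci": dc,
        })
    return rows


def run_pipeline(config: RunConfig | Mapping[str, Any] | str | Path) -> dict:
    """Run every stage; returns the bundle (DataFrames + paths).

    Any stage failure raises :class:`PipelineError` naming the stage;
    tables written by earlier stages are preserved in the output
    directory.
    """
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_yaml(config)
    elif isinstance(config, RunConfig):
        cfg = config
    else:
        cfg = RunConfig.from_dict(config)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"outdir": cfg.outdir}
    checks: dict[str, str] = {}

    def finish_stage(stage: str, df: pd.DataFrame, fname: str, t0: float):
        path = cfg.outdir / fname
        write_table(df, path)
        checks[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
        log.info("stage %s: wrote %s in %.2fs", stage, path, time.time() - t0)

    trajs: dict[str, Trajectory] = {}
    stage = "load"
    try:
        for name, run in cfg.runs.items():
            trajs[name] = _load_run_traj(run)
            _validate_site_rules(name, run, trajs[name])
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "dynamics"
    try:
        t0 = time.time()
        rows = []
        for name, run in cfg.runs.items():
            rows += _dynamics_rows(cfg, name, trajs[name], run)
        dyn = pd.DataFrame(rows)
        bundle["dynamics"] = dyn
        finish_stage(stage, dyn, "dynamics_summary.csv", t0)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "descriptors"
    try:
        t0 = time.time()
        have_bulk = all(
            {"eta_exp", "D_exp", "D_model"} <= set(r) for r in cfg.runs.values()
        )
        if have_bulk:
            rows = []
            for name, run in cfg.runs.items():
                eta_model = viscosity.model_viscosity(
                    run["eta_exp"], run["D_exp"], run["D_model"]
                )
                for _, dr in dyn[dyn["solvent"] == name].iterrows():
                    d_local = dr["D_local_1e5cm2s"]
                    eta_loc = (
                        viscosity.local_viscosity(eta_model, run["D_model"],
                                                  d_local)
                        if d_local > 0 else np.inf
                    )
                    retard = d_local / run["D_model"]
                    rows.append({
                        "solvent": name, "region": dr["region"],
                        "eta_model_mPas": eta_model,
                        "eta_local_mPas": eta_loc,
                        "retardation": retard,
                        "D_local_1e5cm2s": d_local,
                    })
            desc = pd.DataFrame(rows)
            if cfg.water in cfg.runs:
                dwater = {
                    r["region"]: r["D_local_1e5cm2s"] for r in rows
                    if r["solvent"] == cfg.water
                }
                desc["mobility_ratio"] = [
                    r.D_local_1e5cm2s / dwater[r.region]
                    if dwater.get(r.region, 0) > 0 else np.nan
                    for r in desc.itertuples()
                ]
            bundle["descriptors"] = desc
            finish_stage(stage, desc, "descriptors.csv", t0)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "flexibility"
    try:
        t0 = time.time()
        rows = []
        integrated: dict[tuple[str, str, str], float] = {}
        for name in cfg.runs:
            for variant in cfg.rmsf_variants:
                prof = flexibility.rmsf_profile(trajs[name], variant)
                for rname, region in cfg.regions.items():
                    integrated[(name, variant, rname)] = (
                        flexibility.regional_flexibility(prof, region)
                    )
        ref_solvent = cfg.water if cfg.water in cfg.runs else next(iter(cfg.runs))
        for (name, variant, rname), val in integrated.items():
            ref = integrated[(ref_solvent, variant, rname)]
            rows.append({
                "solvent": name, "variant": variant, "region": rname,
                "integrated_rmsf_nm": val,
                "ratio": flexibility.flexibility_ratio(val, ref),
            })
        flex = pd.DataFrame(rows)
        bundle["flexibility"] = flex
        finish_stage(stage, flex, "flexibility.csv", t0)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "correlation"
    try:
        t0 = time.time()
        if (
            "descriptors" in bundle and cfg.water in cfg.runs
            and len(cfg.runs) >= 3
        ):
            sprops = pd.DataFrame([
                {"solvent": n,
                 "eta_model": viscosity.model_viscosity(
                     r["eta_exp"], r["D_exp"], r["D_model"]),
                 "D_bulk": r["D_model"]}
                for n, r in cfg.runs.items()
            ])
            regD = bundle["descriptors"].rename(
                columns={"D_local_1e5cm2s": "D_local"}
            )[["solvent", "region", "D_local"]]
            panels = correlation.build_panels(
                flex, sprops, regD, water=cfg.water
            )
            pf = correlation.panels_to_frame(panels)
            bundle["panels"] = pf
            finish_stage(stage, pf, "correlation_panels.csv", t0)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "msm"
    try:
        if cfg.msm:
            from . import msm as msm_mod

            t0 = time.time()
            ra = cfg.regions[cfg.msm["region_a"]]
            rb = cfg.regions[cfg.msm["region_b"]]
            feats = [
                msm_mod.min_distance_feature(trajs[n], ra, rb)
                for n in cfg.runs
            ]
            model = msm_mod.fit_msm_pipeline(
                feats, dt_ns=cfg.msm.get("dt_ns", 1.0),
                lag_ns=cfg.msm["lag_ns"],
                n_bins=cfg.msm.get("n_bins", 60),
                n_meta=cfg.msm.get("n_meta", 3),
                n_boot=cfg.msm.get("n_boot", 5), seed=cfg.seed,
            )
            bundle["msm"] = model
            path = cfg.outdir / "msm_model.json"
            path.write_text(json.dumps(model.as_jsonable(), indent=1))
            checks["msm_model.json"] = hashlib.sha256(
                path.read_bytes()).hexdigest()
            log.info("stage msm done in %.2fs", time.time() - t0)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "tables": checks,
        "regions": sorted(cfg.regions),
        "solvents": sorted(cfg.runs),
    }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle


def _config_hash(cfg: RunConfig) -> str:
    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in sorted(v.items())
                    if not k.startswith("_") and k != "trajectory"}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (str, int, float, bool)) or v is None:
            return v
        return repr(type(v).__name__)

    payload = {
        "runs": clean(cfg.runs),
        "regions": {n: repr(r) for n, r in sorted(cfg.regions.items())},
        "block_count": cfg.block_count,
        "fit_window": list(cfg.fit_window),
        "origins_stride": cfg.origins_stride,
        "rmsf_variants": list(cfg.rmsf_variants),
        "msm": clean(cfg.msm) if cfg.msm else None,
        "seed": cfg.seed,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
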