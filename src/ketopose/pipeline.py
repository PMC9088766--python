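"""End-to-end pipeline orchestration from a single JSON config.

Stages (``synth`` → ``triage`` / ``competence`` / ``hbonds`` / ``csp`` /
``wham``) run in dependency order; every report carries the config hash,
root seed and package version so that a rerun with the same (config, seed)
is byte-identical.  Per-stage wall time is logged to stderr only — never
written into outputs, which must be reproducible byte-for-byte.

All randomness derives from one root seed via named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_TEMPERATURE
from .csp import csp_report, report_to_frame
from .errors import ConfigError, KetoposeError, ValidationError
from .hbonds import HBondCriteria, Partner, occupancy_table
from .model_io import read_titration_manifest, read_window_file, write_window_file
from .stereo import CompetenceCriteria, competence_summary
from .synthetic import (PoseClusterMix, PotentialSpec, TitrationSpec,
                        TrajectorySpec, gen_competence_trajectory,
                        gen_pose_table, gen_titration_peaklists,
                        gen_umbrella_samples)
from .triage import TriageThresholds, frame_to_poses, poses_to_frame, triage_filter
from .wham import barrier_height, pmf_to_rows, wham_solve, window_ladder

logger = logging.getLogger("ketopose")

_KNOWN_STAGES = ("synth", "triage", "competence", "hbonds", "csp", "wham")
# stages that may consume synth products must run after synth
_ORDER = {name: i for i, name in enumerate(_KNOWN_STAGES)}


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    outdir: Path = Path("ketopose_out")
    options: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        stages = d.get("stages", [])
        options = {k: v for k, v in d.items()
                   if k not in ("stages", "seed", "temperature", "outdir")}
        return cls(stages=list(stages), seed=int(d.get("seed", 0)),
                   temperature=float(d.get("temperature", DEFAULT_TEMPERATURE)),
                   outdir=Path(d.get("outdir", "ketopose_out")),
                   options=options)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def validate(self) -> None:
        if not self.stages:
            raise ConfigError("stage list is empty")
        for s in self.stages:
            if s not in _KNOWN_STAGES:
                raise ConfigError(f"unknown stage {s!r} "
                                  f"(known: {', '.join(_KNOWN_STAGES)})")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("duplicate stages in config")
        for stage, block in self.options.items():
            for key in ("path", "manifest", "poses"):
                p = block.get(key) if isinstance(block, dict) else None
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"stage {stage!r}: input file {p} not found")

    def canonical_json(self) -> str:
        payload = {"stages": self.stages, "seed": self.seed,
                   "temperature": self.temperature, "outdir": str(self.outdir),
                   **self.options}
        return json.dumps(payload, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages and write reports under config.outdir.

    Returns the run report (also written as ``report.json``).  A failing
    stage aborts any later stage that depends on its products, with a clear
    message naming both stages.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = sorted(config.stages, key=lambda s: _ORDER[s])
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__, "temperature": config.temperature}
    report: dict[str, Any] = {**meta, "stages": {}}
    products: dict[str, Any] = {}
    failed: str | None = None

    for stage in stages:
        if failed is not None and stage != "triage":
            # every non-triage stage may consume synth products
            if failed == "synth" and stage in ("competence", "hbonds", "csp", "wham"):
                report["stages"][stage] = {
                    "status": "aborted",
                    "reason": f"dependency stage {failed!r} failed",
                }
                continue
        t0 = time.perf_counter()
        try:
            result = _RUNNERS[stage](config, products, outdir)
            report["stages"][stage] = {"status": "ok", **result}
        except KetoposeError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            failed = stage
        logger.info("stage %s finished in %.2f s", stage,
                    time.perf_counter() - t0)

    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True) + "\n")
    return report


def _opts(config: RunConfig, stage: str) -> dict[str, Any]:
    block = config.options.get(stage, {})
    if not isinstance(block, dict):
        raise ConfigError(f"stage block {stage!r} must be a JSON object")
    return block


def _run_synth(config: RunConfig, products: dict, outdir: Path) -> dict:
    o = _opts(config, "synth")
    seed = _stage_seed(config.seed, "synth")
    result: dict[str, Any] = {}

    n_replicas = int(o.get("n_replicas", 4))
    n_frames = int(o.get("n_frames", 500))
    fraction = float(o.get("fraction_competent", 0.1))
    noise = float(o.get("noise_sd", 0.02))
    criteria = CompetenceCriteria(**o.get("criteria", {}))
    trajs = [
        gen_competence_trajectory(
            TrajectorySpec(n_frames, fraction, noise, seed=seed + i),
            criteria, replica_id=f"r{i}")
        for i in range(n_replicas)
    ]
    products["trajectories"] = trajs
    products["criteria"] = criteria
    result["n_trajectories"] = len(trajs)

    if "poses" in o or o.get("gen_poses", True):
        poses, labels = gen_pose_table(int(o.get("n_poses", 200)),
                                       PoseClusterMix(), seed=seed + 1000)
        products["poses"] = poses
        poses_to_frame(poses).to_csv(outdir / "poses.csv", index=False)
        result["n_poses"] = len(poses)

    if "umbrella" in o:
        u = o["umbrella"]
        potential = PotentialSpec(u.get("form", "double_well"),
                                  u.get("params", {"a": 4.0, "b": 1.0}))
        centers = window_ladder(float(u.get("start", -1.8)),
                                float(u.get("stop", 1.8)),
                                float(u.get("spacing", 0.1)))
        windows = gen_umbrella_samples(
            potential, centers, float(u.get("k", 50.0)),
            int(u.get("n_per_window", 2000)),
            temperature=config.temperature, seed=seed + 2000)
        products["windows"] = windows
        wdir = outdir / "windows"
        wdir.mkdir(exist_ok=True)
        for i, w in enumerate(windows):
            write_window_file(w, wdir / f"window_{i:03d}.txt")
        result["n_windows"] = len(windows)

    if "titration" in o:
        t = o["titration"]
        true_csp = {int(k): tuple(v) for k, v in t.get("true_csp", {}).items()}
        spec = TitrationSpec(true_csp=true_csp, kd=float(t.get("kd", 0.5)),
                             acp_conc=float(t.get("acp_conc", 0.5)),
                             noise_sd=float(t.get("noise_sd", 0.0)),
                             seed=seed + 3000)
        products["peaklists"] = gen_titration_peaklists(spec)
        result["n_titration_points"] = len(products["peaklists"])
    return result


def _run_triage(config: RunConfig, products: dict, outdir: Path) -> dict:
    o = _opts(config, "triage")
    thresholds = TriageThresholds(
        energy_max=float(o.get("energy_max", -90.0)),
        distance_max=float(o.get("distance_max", 9.0)),
        stability_tolerance=float(o.get("stability_tolerance", 0.15)),
        stability_window_ns=float(o.get("stability_window_ns", 4.0)))
    if "poses" in o:
        poses = frame_to_poses(pd.read_csv(o["poses"]))
    elif "poses" in products:
        poses = products["poses"]
    else:
        raise ValidationError("triage stage has no pose table "
                              "(provide 'poses' path or run synth)")
    kept = triage_filter(poses, thresholds)
    poses_to_frame(kept).to_csv(outdir / "triage.csv", index=False)
    return {"n_in": len(poses), "n_kept": len(kept)}


def _run_competence(config: RunConfig, products: dict, outdir: Path) -> dict:
    if "trajectories" not in products:
        raise ValidationError("competence stage needs synth trajectories")
    criteria = products.get("criteria", CompetenceCriteria())
    summary = competence_summary(products["trajectories"], criteria,
                                 config.temperature)
    payload = {
        "fraction": summary.fraction,
        "percent": summary.percent,
        "per_replica_fractions": summary.per_replica_fractions,
        "loo_stderr": summary.loo_stderr,
        "delta_g_kcal_mol": summary.delta_g,
        "temperature_K": summary.temperature,
        "n_frames": summary.n_frames,
        "n_competent": summary.n_competent,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (outdir / "competence.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"fraction": summary.fraction, "delta_g": summary.delta_g}


def _run_hbonds(config: RunConfig, products: dict, outdir: Path) -> dict:
    o = _opts(config, "hbonds")
    if "trajectories" not in products:
        raise ValidationError("hbonds stage needs synth trajectories")
    criteria = HBondCriteria(da_max=float(o.get("da_max", 3.5)),
                             dha_min=float(o.get("dha_min", 135.0)))
    # catalytic contacts on the synthetic roster: Tyr157/Ser144 OH -> O9
    pairs = [
        (Partner(("K", 157, "OH"), (("K", 157, "HH"),)), Partner(("S", 2, "O9"))),
        (Partner(("K", 144, "OG"), (("K", 144, "HG"),)), Partner(("S", 2, "O9"))),
    ]
    tables = [occupancy_table(traj, pairs, criteria)
              for traj in products["trajectories"]]
    merged = (pd.concat(tables).groupby(["donor", "acceptor", "kind"],
                                        as_index=False)["occupancy"].mean()
              .sort_values(["occupancy", "donor"], ascending=[False, True]))
    merged.to_csv(outdir / "hbonds.csv", index=False)
    return {"n_pairs": len(pairs)}


def _run_csp(config: RunConfig, products: dict, outdir: Path) -> dict:
    o = _opts(config, "csp")
    if "manifest" in o:
        series = read_titration_manifest(o["manifest"])
    elif "peaklists" in products:
        series = products["peaklists"]
    else:
        raise ValidationError("csp stage has no peak lists "
                              "(provide 'manifest' or synth titration block)")
    report = csp_report(series, prolines=o.get("prolines", ()))
    report_to_frame(report).to_csv(outdir / "csp.csv", index=False)
    n_perturbed = sum(r.bin in ("yellow", "orange", "red") for r in report)
    return {"n_residues": len(report), "n_perturbed": n_perturbed}


def _run_wham(config: RunConfig, products: dict, outdir: Path) -> dict:
    o = _opts(config, "wham")
    if "manifest" in o:
        mdir = Path(o["manifest"]).parent
        manifest = pd.read_csv(o["manifest"])
        windows = [read_window_file(mdir / str(r["file"]))
                   for _, r in manifest.iterrows()]
    elif "windows" in products:
        windows = products["windows"]
    else:
        raise ValidationError("wham stage has no windows "
                              "(provide 'manifest' or synth umbrella block)")
    pmf = wham_solve(windows, temperature=config.temperature,
                     bin_width=float(o.get("bin_width", 0.02)))
    rows = pmf_to_rows(pmf)
    with open(outdir / "pmf.csv", "w") as fh:
        fh.write("xi_A,free_energy_kcal_mol\n")
        for xi, g in rows:
            fh.write(f"{xi:.6f},{g:.6f}\n")
    result: dict[str, Any] = {"n_windows": len(windows), "n_bins": len(rows)}
    if "reactant_range" in o and "ts_range" in o:
        result["barrier_kcal_mol"] = barrier_height(
            pmf, tuple(o["reactant_range"]), tuple(o["ts_range"]))
    return result


_RUNNERS = {
    "synth": _run_synth,
    "triage": _run_triage,
    "competence": _run_competence,
    "hbonds": _run_hbonds,
    "csp": _run_csp,
    "wham": _run_wham,
}
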