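"""End-to-end orchestration: simulate cohorts, segment, measure, compare.

A run is described by one configuration (YAML-friendly dict): per-cohort
fibre specs, segmentation and spatial parameters, a stats plan, an output
directory and a global seed.  Per-fibre seeds are spawned deterministically
from the global seed, so a rerun with the same configuration reproduces
every output file bit-identically (verified through the manifest hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry, spatial, stats
from .segmentation import SegmentationParams, segment_stack
from .simulate import SyntheticFiberSpec, generate_fiber, render_stack

__all__ = ["RunConfig", "run", "load_config"]

log = logging.getLogger("myonuc.pipeline")

_SPEC_FIELDS = {f.name for f in dataclasses.fields(SyntheticFiberSpec)}


@dataclasses.dataclass
class RunConfig:
    cohorts: list[dict]                    # each: {name, n_fibers, fiber: {...}}
    output_dir: str = "out"
    seed: int = 0
    render: bool = False                   # False: analyze ground-truth centroids
    segmentation: dict = dataclasses.field(default_factory=dict)
    spatial: dict = dataclasses.field(
        default_factory=lambda: {"segment_length": 375.0, "slice_length": 20.0}
    )
    stats_plan: list[dict] = dataclasses.field(
        default_factory=lambda: [
            {"metric": "nuclei_per_100um", "test": "student_t"},
            {"metric": "nn_mean", "test": "student_t"},
            {"metric": "mnd_mean", "test": "student_t"},
        ]
    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stats" in d:
            d["stats_plan"] = d.pop("stats")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if not d.get("cohorts"):
            raise ValueError("config must define at least one cohort")
        return cls(**d)


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _fiber_spec(cohort: dict, seed: int) -> SyntheticFiberSpec:
    params = dict(cohort.get("fiber", {}))
    unknown = set(params) - _SPEC_FIELDS
    if unknown:
        raise ValueError(f"unknown fiber spec keys in cohort "
                         f"{cohort.get('name')}: {sorted(unknown)}")
    for key in ("nucleus_semi_axes", "voxel_size"):
        if key in params:
            params[key] = tuple(params[key])
    if isinstance(params.get("noise_model"), list):
        params["noise_model"] = tuple(params["noise_model"])
    params["seed"] = seed
    return SyntheticFiberSpec(**params)


def _analyze_fiber(spec: SyntheticFiberSpec, cfg: RunConfig,
                   rng: np.random.Generator) -> dict:
    nuclei, geometry = generate_fiber(spec, rng=rng)
    if cfg.render:
        stack = render_stack(nuclei, geometry, spec, rng=rng)
        seg = segment_stack(stack, SegmentationParams(**cfg.segmentation))
        centroids = np.array([n.centroid_3d for n in seg]).reshape(-1, 3)
    else:
        centroids = np.array([n.centroid for n in nuclei]).reshape(-1, 3)

    n = len(centroids)
    seg_len = min(cfg.spatial.get("segment_length", 375.0), spec.fiber_length)
    nn = spatial.nearest_neighbour(centroids)
    mnd = spatial.myonuclear_domain(
        centroids[:, 0] if n else np.empty(0),
        geometry.csa,
        segment_length=seg_len,
        slice_length=cfg.spatial.get("slice_length", 20.0),
        fiber_length=spec.fiber_length,
    )
    return {
        "n_nuclei": n,
        "csa_um2": geometry.csa,
        "volume_per_100um_um3": geometry.volume_per_100um,
        "nuclei_per_100um": morphometry.nuclei_per_100um(n, spec.fiber_length),
        "nuclei_per_volume": (
            n / (geometry.csa * spec.fiber_length) if geometry.csa > 0 else math.nan
        ),
        "nn_mean": nn.nn_mean,
        "nn_sd": nn.nn_sd,
        "mnd_mean": mnd.mnd_mean,
        "mnd_sd": mnd.mnd_sd,
    }


def run(config: RunConfig | dict, output_dir=None) -> dict:
    """Execute a full run; returns (and writes) the output manifest.

    A fibre that fails analysis is logged, skipped, and recorded in the
    manifest; an entirely empty cohort is an error naming the cohort.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log.jsonl", mode="w")
    handler.setFormatter(logging.Formatter(
        '{"time": "%(asctime)s", "level": "%(levelname)s", "msg": %(message)r}'
    ))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    root_ss = np.random.SeedSequence(config.seed)
    cohort_seeds = root_ss.spawn(len(config.cohorts))
    tidy_rows = []
    failures = []
    try:
        for cohort, css in zip(config.cohorts, cohort_seeds):
            name = cohort.get("name", "cohort")
            n_fibers = int(cohort.get("n_fibers", 0))
            if n_fibers < 1:
                raise ValueError(f"cohort '{name}' is empty (n_fibers={n_fibers})")
            log.info(f"cohort {name}: {n_fibers} fibres")
            fiber_seeds = css.spawn(n_fibers)
            for k, fss in enumerate(fiber_seeds):
                seed32 = int(fss.generate_state(1)[0] % (2**31))
                spec = _fiber_spec(cohort, seed32)
                try:
                    row = _analyze_fiber(spec, config, np.random.default_rng(fss))
                except Exception as exc:  # noqa: BLE001 - isolate fibre failures
                    log.warning(f"cohort {name} fibre {k} failed: {exc}")
                    failures.append({"cohort": name, "fiber_id": k, "error": str(exc)})
                    continue
                row.update({"cohort": name, "fiber_id": k, "seed": seed32})
                tidy_rows.append(row)
    finally:
        log.removeHandler(handler)
        handler.close()

    tidy = pd.DataFrame(tidy_rows).sort_values(["cohort", "fiber_id"]).reset_index(drop=True)
    files = {}
    for name, grp in tidy.groupby("cohort"):
        p = out / f"fibers_{name}.csv"
        grp.to_csv(p, index=False, float_format="%.6g")
        files[p.name] = p
    tidy_path = out / "fibers_all.csv"
    tidy.to_csv(tidy_path, index=False, float_format="%.6g")
    files[tidy_path.name] = tidy_path

    stats_rows = []
    cohort_names = [c.get("name", "cohort") for c in config.cohorts]
    for plan in config.stats_plan:
        metric, test = plan["metric"], plan.get("test", "student_t")
        for i in range(len(cohort_names)):
            for j in range(i + 1, len(cohort_names)):
                a = tidy.loc[tidy.cohort == cohort_names[i], metric].dropna() \
                    if len(tidy) else pd.Series(dtype=float)
                b = tidy.loc[tidy.cohort == cohort_names[j], metric].dropna() \
                    if len(tidy) else pd.Series(dtype=float)
                row = {
                    "metric": metric, "test": test,
                    "group_a": cohort_names[i], "group_b": cohort_names[j],
                    "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                    "n_a": len(a), "n_b": len(b),
                }
                try:
                    res = stats.compare_groups(a, b, test)
                    row.update(statistic=res.statistic, p_value=res.p_value)
                except ValueError as exc:
                    log.warning(f"stats skipped for {metric}: {exc}")
                    row.update(statistic=math.nan, p_value=math.nan,
                               note=str(exc))
                stats_rows.append(row)
    stats_df = pd.DataFrame(stats_rows)
    stats_path = out / "stats.csv"
    stats_df.to_csv(stats_path, index=False, float_format="%.6g")
    files[stats_path.name] = stats_path

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_fibers_analyzed": len(tidy),
        "failures": failures,
        "files": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
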