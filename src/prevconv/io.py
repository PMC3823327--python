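"""Delimited-text readers/writers, run configuration, and the pipeline.

All tables are headed CSV; adjacency is an undirected edge list
(area_id_a, area_id_b) validated symmetric on load; draws persist both as a
flat long table (chain, iteration, parameter, value) and as a wide table,
each re-loadable for post-processing.  Coordinates are assumed planar (km);
no CRS handling is attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assessment import dic_report
from .frames import AreaFrame
from .kernels import Grid, KernelSpec
from .model import ModelSpec, PriorSpec, ProcessSpec, model_variant
from .riskmaps import crosstab_classifications, risk_summary
from .sampler import STRUCTURAL_PARAMS, ChainConfig, PosteriorDraws, gelman_rubin, run_mcmc

__all__ = [
    "read_area_frame",
    "write_area_frame",
    "read_adjacency",
    "write_adjacency",
    "save_draws",
    "load_draws",
    "RunConfig",
    "run_pipeline",
    "compare_models",
]

_REQUIRED = ("area_id", "easting", "northing", "count", "offset_prevalence")


def read_area_frame(path, role: str, adjacency_path=None) -> AreaFrame:
    """Load one frame from CSV, preserving row order and validating columns."""
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ids = df["area_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = df["area_id"][df["area_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate area_id {dup!r}")
    off = df["offset_prevalence"].to_numpy(float)
    if np.any(off <= 0):
        bad = int(np.argmax(off <= 0))
        raise ValueError(f"{path}: nonpositive offset_prevalence at row {bad} (id {ids[bad]!r})")
    adjacency = None
    if adjacency_path is not None:
        adjacency = read_adjacency(adjacency_path, ids)
    return AreaFrame(
        role=role,
        ids=ids,
        centroids=df[["easting", "northing"]].to_numpy(float),
        count=df["count"].to_numpy(),
        offset_prevalence=off,
        offset_morbidity=df["offset_morbidity"].to_numpy(float) if "offset_morbidity" in df else None,
        covariate=df["covariate"].to_numpy(float) if "covariate" in df else None,
        adjacency=adjacency,
    )


def write_area_frame(frame: AreaFrame, path, header_comment: str | None = None) -> None:
    out = {
        "area_id": frame.ids,
        "easting": frame.centroids[:, 0],
        "northing": frame.centroids[:, 1],
        "count": frame.count,
        "offset_prevalence": frame.offset_prevalence,
    }
    if frame.offset_morbidity is not None:
        out["offset_morbidity"] = frame.offset_morbidity
    if frame.covariate is not None:
        out["covariate"] = frame.covariate
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(out).to_csv(fh, index=False)


def read_adjacency(path, ids) -> list[np.ndarray]:
    """Edge list (area_id_a, area_id_b) -> per-area neighbour index lists."""
    edges = pd.read_csv(path, comment="#")
    index = {aid: i for i, aid in enumerate(ids)}
    sets: list[set[int]] = [set() for _ in ids]
    for a, b in zip(edges["area_id_a"], edges["area_id_b"]):
        if a not in index or b not in index:
            raise ValueError(f"{path}: edge references unknown area ({a!r}, {b!r})")
        ia, ib = index[a], index[b]
        if ia == ib:
            raise ValueError(f"{path}: self-loop at {a!r}")
        sets[ia].add(ib)
        sets[ib].add(ia)
    return [np.array(sorted(s), dtype=np.int64) for s in sets]


def write_adjacency(frame: AreaFrame, path, header_comment: str | None = None) -> None:
    if frame.adjacency is None:
        raise ValueError("frame has no adjacency")
    rows = []
    for k, nb in enumerate(frame.adjacency):
        for l in nb:
            if k < l:
                rows.append((frame.ids[k], frame.ids[l]))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows, columns=["area_id_a", "area_id_b"]).to_csv(fh, index=False)


def save_draws(draws: PosteriorDraws, out_dir) -> dict[str, Path]:
    """Persist structural draws in wide and long form; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wide = draws.structural_frame()
    wide_path = out_dir / "draws_wide.csv"
    wide.to_csv(wide_path, index=False)
    long = wide.melt(id_vars=["chain", "iteration"], var_name="parameter", value_name="value")
    long_path = out_dir / "draws_long.csv"
    long.to_csv(long_path, index=False)
    return {"wide": wide_path, "long": long_path}


def load_draws(path) -> dict[str, np.ndarray]:
    """Re-load structural draws (wide or long CSV) as name -> (chains, draws)."""
    df = pd.read_csv(path)
    if "parameter" in df.columns:  # long form
        df = df.pivot_table(index=["chain", "iteration"], columns="parameter",
                            values="value").reset_index()
    chains = sorted(df["chain"].unique())
    out = {}
    for name in df.columns:
        if name in ("chain", "iteration"):
            continue
        out[name] = np.stack([
            df.loc[df["chain"] == c].sort_values("iteration")[name].to_numpy()
            for c in chains
        ])
    return out


@dataclass
class RunConfig:
    """Everything one fit needs; defaults reproduce the Model 1 settings
    (standard normal kernel, normal process, diffuse priors)."""

    source_path: str = ""
    target_path: str = ""
    adjacency_path: str = ""
    out_dir: str = "run"
    model: int = 1
    kernel_scale: float = 1.0
    process_df: float = 5.0
    precision_shape: float = 0.001
    precision_rate: float = 0.001
    coeff_variance: float = 1000.0
    grid_spacing: float = 2.0
    n_chains: int = 2
    n_iter: int = 5000
    burn_fraction: float = 0.5
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    hotspot_threshold: float = 0.8
    cluster_threshold: float = 0.25
    regional_rate: float = 0.046
    psrf_threshold: float = 1.1

    def model_spec(self) -> ModelSpec:
        priors = PriorSpec(precision_shape=self.precision_shape,
                           precision_rate=self.precision_rate,
                           coeff_variance=self.coeff_variance)
        spec = model_variant(self.model, priors=priors)
        return ModelSpec(
            kernel=KernelSpec(family=spec.kernel.family, scale=self.kernel_scale),
            process=ProcessSpec(family=spec.process.family, df=self.process_df),
            priors=priors,
        )

    def chain_config(self) -> ChainConfig:
        return ChainConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                           burn_fraction=self.burn_fraction, thin=self.thin,
                           seed=self.seed, target_accept=self.target_accept)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig):
    """generate-free pipeline: read data, fit, assess, classify, write artifacts.

    Writes draws (wide + long), dic.csv, risk_summary.csv, convergence.csv
    and run.log into ``config.out_dir``; returns (draws, DicReport,
    RiskSummary, psrf dict).  Deterministic given the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash: {config.digest()}", f"seed: {config.seed}"]

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    source = _stage("read_source", lambda: read_area_frame(config.source_path, "source"))
    target = _stage("read_target", lambda: read_area_frame(
        config.target_path, "target",
        adjacency_path=config.adjacency_path or None))
    pts = np.vstack([source.centroids, target.centroids])
    grid = Grid.regular((pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max()),
                        spacing=config.grid_spacing)
    spec = config.model_spec()
    draws = _stage("fit", lambda: run_mcmc(source, target, grid, spec, config.chain_config()))
    save_draws(draws, out)
    for name, rate in sorted(draws.acceptance.items()):
        log_lines.append(f"acceptance[{name}]: {rate:.3f}")

    report = _stage("assess", lambda: dic_report(draws, source, target))
    report.to_frame(label=f"model{config.model}").to_csv(out / "dic.csv", index=False)

    summary = _stage("classify", lambda: risk_summary(
        draws, target, config.regional_rate,
        hotspot_threshold=config.hotspot_threshold,
        cluster_threshold=config.cluster_threshold))
    summary.table.to_csv(out / "risk_summary.csv", index=False)

    psrf = (gelman_rubin(draws) if config.n_chains >= 2
            else {name: float("nan") for name in STRUCTURAL_PARAMS})
    conv = pd.DataFrame({"parameter": list(psrf), "psrf": list(psrf.values())})
    conv["converged"] = conv["psrf"] < config.psrf_threshold
    conv.to_csv(out / "convergence.csv", index=False)
    worst = max((v for v in psrf.values() if np.isfinite(v)), default=float("nan"))
    log_lines.append(f"max_psrf: {worst:.4f}")
    log_lines.append(f"converged: {bool(worst < config.psrf_threshold)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    config.to_yaml(out / "config.yaml")
    return draws, report, summary, psrf


def compare_models(run_dirs) -> dict[str, object]:
    """Side-by-side DIC table plus pairwise co-location crosstabs vs run 1.

    All runs must classify the same target frame (same area_id set, same
    order).  Returns {"dic": DataFrame, "hotspot_crosstabs": {...},
    "cluster_crosstabs": {...}} keyed by run-directory name.
    """
    run_dirs = [Path(d) for d in run_dirs]
    if len(run_dirs) < 2:
        raise ValueError("need at least two runs to compare")
    dics, summaries = [], []
    for d in run_dirs:
        dics.append(pd.read_csv(d / "dic.csv").assign(run=d.name))
        summaries.append(pd.read_csv(d / "risk_summary.csv"))
    base_ids = summaries[0]["area_id"]
    for d, s in zip(run_dirs[1:], summaries[1:]):
        if not base_ids.equals(s["area_id"]):
            raise ValueError(f"run {d} classifies a different target frame")
    hot, clu = {}, {}
    base = summaries[0]
    for d, s in zip(run_dirs[1:], summaries[1:]):
        hot[d.name] = crosstab_classifications(s["hotspot"], base["hotspot"])
        clu[d.name] = crosstab_classifications(s["cluster_centre"], base["cluster_centre"])
    return {"dic": pd.concat(dics, ignore_index=True),
            "hotspot_crosstabs": hot, "cluster_crosstabs": clu}
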