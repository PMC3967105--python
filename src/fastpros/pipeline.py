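"""End-to-end pipeline: prepare → reduce → screen → refine → cluster.

Per-target stages are independent; a failure for one target is recorded
in the manifest and does not abort the run.  All outputs are CSV, JSON
or Newick text files, listed with SHA-256 checksums in
``manifest.json`` so an unchanged configuration reproduces byte-
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .environment import EnvironmentConfig
from .exceptions import ConfigurationError
from .io import add_target_exporter, apply_environment, read_model, resolve_target
from .optknock import fastpros_then_optknock
from .reduction import DEFAULT_PROTECTED_GENES, reduce_model
from .screening import ScreeningConfig, min_knockout_histogram, screen
from .similarity import cluster_targets, shared_units

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-friendly)."""

    model_path: str
    targets: list[str]
    out_dir: str
    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    k_list: tuple[int, ...] = (3, 5, 10)
    top_n: int = 30
    protected_genes: tuple[str, ...] = tuple(sorted(DEFAULT_PROTECTED_GENES))
    cluster_method: str = "average"
    cluster_cut_height: float | None = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.k_list):
            raise ValueError("k_list values must be >= 0")
        if not self.targets:
            raise ValueError("at least one target is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        env = EnvironmentConfig(**raw.pop("env", {}))
        scr = ScreeningConfig(**raw.pop("screening", {}))
        raw["k_list"] = tuple(raw.get("k_list", (3, 5, 10)))
        raw["protected_genes"] = tuple(
            raw.get("protected_genes", sorted(DEFAULT_PROTECTED_GENES))
        )
        return cls(env=env, screening=scr, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    model_path = Path(cfg.model_path)
    if not model_path.exists():
        raise ConfigurationError(f"model path does not exist: {model_path}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    base_model = read_model(model_path)
    manifest: dict = {"config": {"model_path": str(model_path), "targets": cfg.targets},
                      "targets": {}, "files": {}}
    screening_rows = []
    optknock_rows = []
    best_sets: dict[str, frozenset[str]] = {}
    results_by_target = {}

    for target in cfg.targets:
        try:
            model = base_model.copy()
            add_target_exporter(model, target)
            apply_environment(model, cfg.env)
            resolve_target(model, target)
            reduced = reduce_model(
                model, cfg.env, protected_genes=frozenset(cfg.protected_genes)
            )
            screening = screen(reduced.model, cfg.env, target, reduced.units, cfg.screening)
            results_by_target[target] = screening
            for rec in screening.candidates:
                screening_rows.append({
                    "target": target,
                    "knockout_units": ";".join(sorted(rec.knockouts)),
                    "set_size": len(rec.knockouts),
                    "f_target": _fmt(rec.f_target),
                    "classification": rec.classification,
                })
            refined = fastpros_then_optknock(
                reduced.model, cfg.env, target, reduced.units,
                cfg=cfg.screening, k_list=cfg.k_list, top_n=cfg.top_n,
            )
            best = None
            for k in cfg.k_list:
                res = refined[k]
                optknock_rows.append({
                    "target": target,
                    "K": k,
                    "status": res.status,
                    "knockout_units": ";".join(sorted(res.knockout_units)),
                    "growth": _fmt(res.growth),
                    "target_flux": _fmt(res.target_flux_at_biomass_max),
                    "yield_fraction_tmy": _fmt(res.yield_fraction_tmy),
                })
                if res.status == "optimal" and (
                    best is None or res.target_flux_at_biomass_max > best.target_flux_at_biomass_max
                ):
                    best = res
            if best is not None and best.knockout_units:
                best_sets[target] = best.knockout_units
            manifest["targets"][target] = {
                "status": "ok",
                "n_candidates": len(screening.candidates),
                "min_knockouts": screening.min_knockouts,
            }
        except Exception as exc:  # per-target isolation
            logger.exception("target %s failed", target)
            manifest["targets"][target] = {"status": "failed", "error": str(exc)}

    pd.DataFrame(
        screening_rows,
        columns=["target", "knockout_units", "set_size", "f_target", "classification"],
    ).to_csv(out / "screening.csv", index=False)
    pd.DataFrame(
        optknock_rows,
        columns=["target", "K", "status", "knockout_units", "growth",
                 "target_flux", "yield_fraction_tmy"],
    ).to_csv(out / "optknock.csv", index=False)

    if results_by_target:
        hist, not_producible = min_knockout_histogram(results_by_target)
        (out / "min_knockouts.json").write_text(
            json.dumps({"histogram": hist, "not_producible": not_producible},
                       indent=2, sort_keys=True) + "\n"
        )

    if len(best_sets) >= 2:
        clustering = cluster_targets(
            best_sets, method=cfg.cluster_method, cut_height=cfg.cluster_cut_height
        )
        (out / "targets.nwk").write_text(clustering.newick + "\n")
        clustering.similarity.to_dataframe().to_csv(out / "similarity.csv")
        if clustering.labels is not None:
            shared = shared_units(best_sets, clustering.labels)
            (out / "shared_knockouts.json").write_text(
                json.dumps({str(k): v for k, v in shared.items()},
                           indent=2, sort_keys=True) + "\n"
            )

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    manifest["failed_targets"] = [
        t for t, info in manifest["targets"].items() if info["status"] == "failed"
    ]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
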