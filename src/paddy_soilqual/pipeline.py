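"""End-to-end orchestration: data -> indices -> effects -> GRA -> report.

The pipeline either ingests the four tidy tables or simulates them, then
computes aggregate-stability indices, alpha diversity, per-variable
treatment summaries and the grey relational ranking, writing one CSV per
stage plus a Markdown report and a JSON run log (versions, seed, config
hash). The report only reformats CSV cells; it never recomputes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregates import compute_aggregate_indices
from .datamodel import TaxonCountTable
from .diversity import compute_diversity_indices
from .effects import TreatmentEffects, correlation_matrix
from .errors import ConfigError, PaddySoilError
from .gra import GreyRelationalAnalysis
from .io import read_count_table, read_tidy_table
from .synth import (
    SynthConfig,
    default_calibration,
    generate_dataset,
    monotone_calibration,
    write_dataset,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "build_long_table",
    "build_grey_matrix",
    "DEFAULT_GRA_INDICES",
]

log = logging.getLogger("paddy_soilqual")

#: Index set of the default treatment-ranking matrix; each appears once per
#: depth. pH is excluded by default (its optimum is interior, not extreme)
#: and diversity columns are opt-in.
DEFAULT_GRA_INDICES = (
    "SOM", "TN", "TP", "AN", "AP",
    "r025", "mwd", "gmd",
    "bacterial_copies", "fungal_copies",
)
DIVERSITY_GRA_INDICES = ("simpson", "pielou")


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` (paths) or ``simulate`` must be present."""

    out_dir: str | Path = "results"
    inputs: dict[str, str] | None = None
    simulate: dict | None = None
    control: str = "RT"
    gra_mode: str = "deng_standard"
    gra_rho: float = 0.5
    gra_include_diversity: bool = False
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError(
                "config must declare exactly one of 'inputs' and 'simulate'"
            )
        if self.inputs is not None:
            missing = {"sieve", "chem", "copies", "counts"} - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs missing table path(s): {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        block = dict(self.simulate or {})
        preset = block.pop("preset", "default")
        if preset == "default":
            cfg = default_calibration()
        elif preset == "monotone":
            cfg = monotone_calibration()
        else:
            raise ConfigError(f"unknown simulate preset {preset!r}")
        cfg.seed = int(self.seed)
        for key, value in block.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown simulate key {key!r}")
            setattr(cfg, key, value)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PaddySoilError as exc:
                raise PaddySoilError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def build_long_table(
    chem: pd.DataFrame,
    copies: pd.DataFrame,
    aggregates: pd.DataFrame,
    diversity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack per-sample tables into variable/depth/treatment/value rows."""
    ids = ["sample_id", "treatment", "depth", "replicate"]
    pieces = []
    for df in (chem, copies, aggregates):
        value_cols = [
            c for c in df.columns if c not in ids and not c.startswith("W_")
        ]
        pieces.append(df.melt(id_vars=ids, value_vars=value_cols, var_name="variable"))
    if diversity is not None:
        merged = diversity.merge(chem[ids], on="sample_id", how="inner")
        pieces.append(
            merged.melt(
                id_vars=ids,
                value_vars=["richness", "shannon", "simpson", "pielou"],
                var_name="variable",
            )
        )
    return pd.concat(pieces, ignore_index=True)


def build_grey_matrix(
    summary: pd.DataFrame,
    indices: tuple[str, ...] = DEFAULT_GRA_INDICES,
) -> pd.DataFrame:
    """Treatment x index matrix of means; depths become separate columns."""
    sub = summary[summary["variable"].isin(indices)]
    wide = sub.pivot_table(index="treatment", columns=["variable", "depth"],
                           values="mean", sort=False)
    wide.columns = [f"{v}@{d}" for v, d in wide.columns]
    # stable column order: index list order, then depth
    depths = sorted({c.split("@")[1] for c in wide.columns})
    ordered = [
        f"{v}@{d}" for v in indices for d in depths if f"{v}@{d}" in wide.columns
    ]
    return wide[ordered]


@_stage("ingest")
def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs or {}
    sieve = read_tidy_table(paths["sieve"], "sieve")
    chem = read_tidy_table(paths["chem"], "chem")
    copies = read_tidy_table(paths["copies"], "copies")
    counts = read_count_table(paths["counts"])
    return sieve, chem, copies, counts


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the paths of the written artifacts."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        synth_cfg = config.synth_config()
        log.info("simulating dataset (seed=%d)", synth_cfg.seed)
        data = generate_dataset(synth_cfg)
        write_dataset(data, out_dir / "data", synth_cfg)
        sieve = data["sieve"]
        chem = data["chem"]
        copies = data["copies"]
        counts: TaxonCountTable = data["counts"]  # type: ignore[assignment]
    else:
        sieve, chem, copies, counts = _load_inputs(config)

    aggregates = _stage("aggregates")(compute_aggregate_indices)(sieve)
    diversity = _stage("diversity")(compute_diversity_indices)(counts)

    long = build_long_table(chem, copies, aggregates, diversity)
    effects = _stage("effects")(
        lambda: TreatmentEffects(control=config.control, alpha=config.alpha).fit(long)
    )()

    indices = DEFAULT_GRA_INDICES + (
        DIVERSITY_GRA_INDICES if config.gra_include_diversity else ()
    )
    matrix = build_grey_matrix(effects.summary_, indices)
    gra = _stage("gra")(
        lambda: GreyRelationalAnalysis(
            mode=config.gra_mode, rho=config.gra_rho
        ).fit(matrix)
    )()

    wide_samples = chem.merge(
        copies.drop(columns=["treatment", "depth", "replicate"]), on="sample_id"
    ).merge(
        aggregates[["sample_id", "r025", "mwd", "gmd"]], on="sample_id"
    )
    corr_r, corr_p = correlation_matrix(
        wide_samples.drop(columns=["replicate"])
    )

    artifacts: dict[str, Path] = {}
    writes = {
        "aggregates": aggregates,
        "diversity": diversity,
        "effects": effects.summary_,
        "gra": gra.result_table().reset_index(names="treatment"),
        "correlation_r": corr_r,
        "correlation_p": corr_p,
    }
    for name, df in writes.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=name.startswith("correlation"))
        artifacts[name] = path

    report = _render_report(config, effects.summary_, gra)
    report_path = out_dir / "report.md"
    report_path.write_text(report)
    artifacts["report"] = report_path

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["out_dir"] = str(cfg_dict["out_dir"])
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    run_log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = log_path
    return artifacts


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    """Minimal GitHub-style pipe table (values formatted, not recomputed)."""
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = list(map(str, df.columns))
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)


def _render_report(
    config: PipelineConfig, summary: pd.DataFrame, gra: GreyRelationalAnalysis
) -> str:
    parts = ["# Soil quality evaluation report", ""]
    parts.append(f"Control treatment: **{config.control}**; "
                 f"GRA mode: **{config.gra_mode}** (rho={config.gra_rho}).")
    parts.append("")
    parts.append("## Treatment means and percent change vs control")
    for (var, depth), grp in summary.groupby(["variable", "depth"], sort=False):
        parts.append(f"\n### {var} @ {depth}\n")
        cols = ["treatment", "n", "mean", "sd",
                "percent_change_vs_control", "tukey_letter"]
        parts.append(_md_table(grp[cols]))
    parts.append("\n## Grey relational ranking\n")
    table = gra.result_table().reset_index(names="treatment")
    parts.append(_md_table(table))
    best = table.loc[table["rank"] == 1, "treatment"].iloc[0]
    ordering = " > ".join(
        table.sort_values("rank")["treatment"].tolist()
    )
    parts.append(f"\nOverall ranking: {ordering}. "
                 f"Highest grey relational degree: **{best}**.")
    parts.append("")
    return "\n".join(parts)
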