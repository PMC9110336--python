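"""End-to-end orchestration: ingest -> covariates -> fit -> compare ->
summarize -> predict, under one YAML config with subset refits.

A run is a pure function of (inputs, config, seed): rerunning reproduces all
non-timestamp outputs bit for bit.  Subset filters (exclude societies,
exclude age classes) implement robustness refits; covariates are z-scored
within the retained subset by default so coefficient scales stay comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ModelSpec
from .covariates import add_zscores
from .inference import (
    McmcConfig,
    build_dataset,
    compare,
    fit,
    summarize_fixed_effects,
)
from .observations import (
    MIKEA_MIDPOINT_AGE,
    ActivityCodeMap,
    expand_observations,
    load_children,
    time_allocation_long,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    observations: str
    children: str
    societies: str
    out_dir: str
    code_map: str | None = None
    models: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    chains: int = 3
    iterations: int = 2000
    warmup: int | None = None
    seed: int = 1
    exclude_societies: list[str] = field(default_factory=list)
    exclude_age_classes: list[str] = field(default_factory=list)
    restandardize: bool = True
    random_effects: bool = True

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in (1, 2, 3, 4, 5)]
        if bad:
            raise ValueError(f"model ids must be in 1..5, got {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def mcmc(self) -> McmcConfig:
        return McmcConfig(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def apply_subset(
    records: pd.DataFrame,
    children: pd.DataFrame,
    societies: pd.DataFrame,
    exclude_societies: list[str],
    exclude_age_classes: list[str],
    restandardize: bool = True,
):
    """Drop excluded societies / age classes everywhere; optionally recompute
    covariate z-scores over the retained societies."""
    if exclude_societies:
        children = children[~children["society_id"].isin(exclude_societies)]
        societies = societies[~societies["society_id"].isin(exclude_societies)]
    if exclude_age_classes:
        children = children[~children["age_class"].isin(exclude_age_classes)]
    records = records[records["child_id"].isin(set(children["child_id"]))]
    if restandardize and (exclude_societies or exclude_age_classes):
        societies = add_zscores(
            societies.drop(columns=[c for c in societies.columns if c.endswith("_z")])
        )
    return records.reset_index(drop=True), children.reset_index(drop=True), societies.reset_index(drop=True)


def descriptive_report(
    records: pd.DataFrame, children: pd.DataFrame
) -> pd.DataFrame:
    """Per-society sample summary: roster size, % girls, mean (SD) age with
    midpoint imputation for labelled children, mean (SD) observations/child."""
    if "age_for_description" not in children.columns:
        children = children.copy()
        children["age_for_description"] = [
            MIKEA_MIDPOINT_AGE[row.age_class]
            if not (row.age_years == row.age_years and row.age_years is not None)
            else row.age_years
            for row in children.itertuples()
        ]
    obs_per_child = records.groupby("child_id").size()
    children = children.merge(
        obs_per_child.rename("n_obs"), left_on="child_id", right_index=True, how="left"
    ).fillna({"n_obs": 0})
    rows = []
    for sid, grp in children.groupby("society_id"):
        rows.append(
            {
                "society_id": sid,
                "n_children": len(grp),
                "pct_girls": 100.0 * (grp["gender"] == "girl").mean(),
                "mean_age": grp["age_for_description"].mean(),
                "sd_age": grp["age_for_description"].std(ddof=1),
                "mean_obs_per_child": grp["n_obs"].mean(),
                "sd_obs_per_child": grp["n_obs"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        raw = pd.read_csv(
            config.observations, dtype={"society_id": str, "child_id": str}
        )
        code_map = (
            ActivityCodeMap.from_csv(config.code_map)
            if config.code_map
            else ActivityCodeMap.identity()
        )
        records = expand_observations(raw, code_map)
        children = load_children(config.children)
        societies = pd.read_csv(config.societies, dtype={"society_id": str})

        stage = "subset"
        records, children, societies = apply_subset(
            records,
            children,
            societies,
            config.exclude_societies,
            config.exclude_age_classes,
            config.restandardize,
        )

        stage = "descriptives"
        societies.to_csv(out / "society_profiles.csv", index=False)
        descriptive_report(records, children).to_csv(
            out / "sample_summary.csv", index=False
        )
        time_allocation_long(records, children).to_csv(
            out / "time_allocation.csv", index=False
        )

        fits = {}
        for model_id in config.models:
            stage = f"fit_model_{model_id}"
            spec = ModelSpec.for_model(model_id)
            dataset = build_dataset(records, children, societies, spec)
            result = fit(
                spec,
                dataset,
                config.mcmc(),
                random_effects=config.random_effects,
            )
            fit_dir = out / f"model_{model_id}"
            result.to_dir(fit_dir)
            summarize_fixed_effects(result).to_csv(
                out / f"coefficients_model{model_id}.csv", index=False
            )
            fits[f"model_{model_id}"] = result

        stage = "compare"
        if fits:
            compare(fits).to_csv(out / "comparison.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    outputs = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "models": config.models,
        "exclude_societies": config.exclude_societies,
        "exclude_age_classes": config.exclude_age_classes,
        "n_records": int(len(records)),
        "n_children": int(len(children)),
        "n_societies": int(len(societies)),
        "outputs": {name: _sha256(out / name) for name in outputs},
        "converged": {name: bool(f.converged) for name, f in fits.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
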