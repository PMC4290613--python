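"""End-to-end orchestration: one config, one seed, reproducible artifacts.

``run_fit`` composes the stages (descriptors → variance filter → split →
stepwise selection → PLS → validation) and writes every intermediate artifact
to the output directory; ``run_screen`` enumerates a substituent library,
predicts with a saved model and exports the ranked hits.  Every delimited or
text artifact starts with a header line carrying the config hash and the run
seed, so reruns can be checked for bit-identity.
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

from . import dataset as _ds
from . import descriptors as _desc
from .chemistry import ARYLTHIOINDOLE, Substituent, parse_substituent, read_pool_file
from .errors import ConfigError, DataError
from .library import (SubstituentPool, entries_to_dataframe,
                      enumerate_assignments, export_sdf, score_library)
from .model import GroupQSAR
from .modeling import FittedModel, SelectionConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured configuration for a full model-building run."""

    series_path: str = ""
    sites: tuple[str, ...] = ("R4", "R5", "R6")
    split: _ds.SplitSpec = field(default_factory=lambda: _ds.SplitSpec(
        mode="random", training_fraction=0.8))
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    variance_cutoff: float = 0.1
    acceptor_rule: str = "NO"
    n_components: int | None = None
    n_permutations: int = 100
    pool_paths: dict[str, str] = field(default_factory=dict)
    top_k: int | None = None
    max_extrapolation: float | None = None
    output_dir: str = "gqsar_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        kwargs = dict(raw)
        if "split" in kwargs:
            kwargs["split"] = _ds.SplitSpec(**{
                k: tuple(v) if k == "test_ids" else v
                for k, v in kwargs["split"].items()})
        if "selection" in kwargs:
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        if "sites" in kwargs:
            kwargs["sites"] = tuple(kwargs["sites"])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps({
            "series_path": self.series_path, "sites": list(self.sites),
            "split": vars(self.split) | {"test_ids": list(self.split.test_ids)},
            "selection": vars(self.selection),
            "variance_cutoff": self.variance_cutoff,
            "acceptor_rule": self.acceptor_rule,
            "n_components": self.n_components,
            "n_permutations": self.n_permutations,
            "pool_paths": self.pool_paths, "top_k": self.top_k,
            "max_extrapolation": self.max_extrapolation,
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _header(config: RunConfig) -> str:
    return f"# gqsar config_hash={config.config_hash()} seed={config.seed}\n"


def _write_text(path: Path, config: RunConfig, body: str) -> None:
    path.write_text(_header(config) + body)


def _write_frame(path: Path, config: RunConfig, df: pd.DataFrame, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", float_format="%.10g", **kwargs)


def run_fit(config: RunConfig, series=None):
    """Fit + validate from a config; returns (results, report) and writes artifacts.

    ``series`` may be passed directly (e.g. a synthetic series); otherwise it
    is read from ``config.series_path``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if series is None:
        if not config.series_path:
            raise ConfigError("config.series_path is required")
        series = _ds.read_series_table(config.series_path, config.sites)
    logger.info("series: %d compounds", len(series))

    split_spec = config.split
    if split_spec.mode == "random" and split_spec.seed == 0:
        split_spec = _ds.SplitSpec(mode="random",
                                   training_fraction=split_spec.training_fraction,
                                   seed=config.seed)
    train, test = _ds.split(series, split_spec)
    logger.info("split: %d training / %d test", len(train), len(test))

    X_all = _desc.descriptor_block(series, config.sites, config.acceptor_rule)
    _write_frame(out / "descriptors.tsv", config, X_all)

    model = GroupQSAR.from_series(train, config.sites,
                                  acceptor_rule=config.acceptor_rule,
                                  selection=config.selection,
                                  variance_cutoff=config.variance_cutoff)
    results = model.fit(n_components=config.n_components)
    logger.info("selected %d descriptors, %d latent components, dropped %d invariable",
                len(results.selected), results.n_components,
                len(results.removed_columns))

    test_X = X_all.loc[[c.id for c in test]] if test else None
    test_y = [c.pic50 for c in test] if test else None
    report = results.validate(test_X, test_y)
    if config.n_permutations > 0:
        report.randomization = results.y_randomization(
            n_permutations=config.n_permutations, seed=config.seed)

    results.fitted.save(out / "model.json")
    _write_text(out / "selection_trace.txt", config, "\n".join(results.trace) + "\n")
    _write_text(out / "summary.txt", config, results.summary() + "\n")
    _write_text(out / "validation.txt", config, report.render() + "\n")
    _write_frame(out / "loo_predictions.tsv", config, pd.DataFrame({
        "id": [c.id for c in train],
        "actual": [c.pic50 for c in train],
        "loo_predicted": results.loo_predictions,
    }), index=False)
    return results, report


def _load_pools(config: RunConfig) -> list[SubstituentPool]:
    if not config.pool_paths:
        raise ConfigError("no substituent pools configured")
    pools = []
    for site, path in sorted(config.pool_paths.items()):
        members = read_pool_file(path, site)
        pools.append(SubstituentPool(site_label=site, members=tuple(members)))
    return pools


def run_screen(config: RunConfig, model_path, template=None):
    """Enumerate, predict and rank the configured library with a saved model."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fitted = FittedModel.load(model_path)
    pools = _load_pools(config)
    model_sites = {name.split("-", 1)[0] for name in fitted.descriptor_names}
    pooled = {p.site_label for p in pools}
    missing = sorted(model_sites - pooled)
    if missing:
        raise ConfigError(f"model needs descriptors at sites {missing} "
                          f"but no pool covers them")
    entries = score_library(enumerate_assignments(pools), fitted,
                            top_k=config.top_k,
                            max_extrapolation=config.max_extrapolation,
                            acceptor_rule=config.acceptor_rule)
    logger.info("ranked %d library entries", len(entries))
    df = entries_to_dataframe(entries)
    _write_frame(out / "library_ranked.tsv", config, df, index=False)
    export_sdf(entries, template or ARYLTHIOINDOLE, out / "library_ranked.sdf")
    return entries
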