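"""Pipeline orchestration: local and server workflows, config and logging.

The full analysis is four stages glued end to end:

    preprocess (OOB filter + discretization)
      -> combinatorics (full-length counting + neutral-state expansion)
      -> stats (frequency tests, significance filter)
      -> independence (similarity network, representatives, confidence)

Two workflows share this code path.  The *local* workflow is for panels whose
projected phenotype table fits in memory; it refuses to start when the
projection exceeds a configurable budget.  The *server* workflow streams
counts to disk chunks and computes statistics chunk by chunk, so memory never
scales with the number of phenotypes.  Both produce identical tables on
inputs small enough for either.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import (
    ConfigurationError,
    DataError,
    EventTable,
    MarkerPanel,
    apply_oob_filter,
    discretize_events,
    read_events,
    read_panel_csv,
)
from .combinatorics import (
    ChunkManifest,
    CountingConfig,
    CountTable,
    PhenotypeCode,
    count_full_length,
    decode_codes,
    expand_neutral,
    find_phenotypes_in_files,
    parse_phenotype,
    projected_phenotype_count,
)
from .stats import (
    annotation_mode,
    evaluate_phenotypes,
    filter_significant,
    read_annotation,
)
from .independence import IndependenceConfig, find_independent_phenotypes

log = logging.getLogger("cytocomb")

__all__ = [
    "RunConfig",
    "load_config",
    "setup_logging",
    "concatenate_samples",
    "run_pipeline",
    "PipelineError",
]

DEFAULT_MEMORY_BUDGET = 2_000_000  # phenotypes the local workflow will hold


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``workflow`` selects local (in-memory, budget-guarded) or server
    (chunked, unbounded phenotype count) processing.  ``parent`` is a
    phenotype string; frequencies are then relative to that population.
    """

    events: list[str] = field(default_factory=list)
    thresholds: str = ""
    annotation: str = ""
    output: str = "cytocomb_out"
    max_length: int = 0  # 0 = number of markers
    min_count: int = 0
    min_sample_fraction: float = 0.0
    parent: str = ""
    chunk_size: int = 100_000
    test_mode: str = ""  # "" = infer from annotation columns
    p_threshold: float = 0.05
    n_subnetworks: int = 10
    community_seed: int = 0
    match_states: bool = True
    max_network_size: int = 500
    threads: int = 1
    workflow: str = "local"
    memory_budget: int = DEFAULT_MEMORY_BUDGET

    def __post_init__(self) -> None:
        if self.workflow not in {"local", "server"}:
            raise ConfigurationError(f"unknown workflow {self.workflow!r}")
        if self.threads < 1:
            raise ConfigurationError("threads must be >= 1")


_BOOL = {"true": True, "false": False, "yes": True, "no": False, "1": True, "0": False}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat ``key = value`` config file; keyword overrides win.

    Lines starting with ``#`` are comments; ``events`` takes a
    comma-separated list.  Precedence: overrides (CLI) > file > defaults.
    """
    values: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"config line not key = value: {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "events":
            values[key] = [v.strip() for v in val.split(",") if v.strip()]
        elif key in {"max_length", "min_count", "chunk_size", "n_subnetworks",
                     "community_seed", "threads", "memory_budget",
                     "max_network_size"}:
            values[key] = int(val)
        elif key in {"min_sample_fraction", "p_threshold"}:
            values[key] = float(val)
        elif key == "match_states":
            values[key] = _BOOL[val.lower()]
        else:
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def setup_logging(log_file: str | Path | None = None) -> None:
    """Console + optional run-log-file logging with timestamps."""
    logger = logging.getLogger("cytocomb")
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def concatenate_samples(
    paths: Sequence[str | Path],
    annotation: pd.DataFrame,
    panel: MarkerPanel,
) -> list[EventTable]:
    """Load event files, key them by sample id and harmonize marker columns.

    The sample id is the file stem and must appear in the annotation.  Columns
    are reordered to panel order; channels absent from the panel are dropped
    with a warning; a panel marker missing from a file is an error.
    """
    known = set(annotation["sample_id"].astype(str))
    missing = [Path(p).stem for p in paths if Path(p).stem not in known]
    if missing:
        raise ConfigurationError(
            f"samples missing from the annotation: {missing}"
        )
    tables = []
    for p in paths:
        t = read_events(p)
        absent = [m for m in panel.names if m not in t.values.columns]
        if absent:
            raise ConfigurationError(
                f"sample {t.sample_id!r}: panel markers missing from file: {absent}"
            )
        extra = [c for c in t.values.columns if c not in panel.names]
        if extra:
            log.warning("sample %s: dropping unused channels %s", t.sample_id, extra)
        tables.append(EventTable(t.sample_id, t.values[panel.names]))
    return tables


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    cfg: RunConfig,
    tables: list[EventTable] | None = None,
    panel: MarkerPanel | None = None,
    annotation: pd.DataFrame | None = None,
) -> Path:
    """Execute preprocess -> counting -> stats -> independence; write outputs.

    Inputs are read from the paths in ``cfg`` unless already-loaded objects
    are passed in.  The output directory receives ``counts/`` (chunked
    phenotype counts + manifest), ``stats.tsv``, ``independent.tsv``,
    ``run.log`` and ``manifest.json``; an exception leaves the manifest
    marked incomplete with the failing stage named.
    """
    out = Path(cfg.output)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")
    manifest: dict = {
        "tool": "cytocomb",
        "version": __version__,
        "config": asdict(cfg),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "complete": False,
        "tallies": {},
    }
    manifest_path = out / "manifest.json"

    def save_manifest() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=1))

    save_manifest()
    try:
        # ---- inputs -------------------------------------------------------
        if panel is None:
            panel = read_panel_csv(cfg.thresholds)
        if annotation is None:
            annotation = read_annotation(cfg.annotation)
        if tables is None:
            tables = concatenate_samples(cfg.events, annotation, panel)
        mode = cfg.test_mode or annotation_mode(annotation)
        max_length = cfg.max_length or len(panel)
        parent = parse_phenotype(cfg.parent, panel) if cfg.parent else None
        counting = CountingConfig(
            max_length=max_length,
            min_count=cfg.min_count,
            min_sample_fraction=cfg.min_sample_fraction,
            parent=parent,
            chunk_size=cfg.chunk_size,
        )

        projected = projected_phenotype_count(panel, max_length)
        if cfg.workflow == "local" and projected > cfg.memory_budget:
            raise ConfigurationError(
                f"projected {projected} phenotypes exceed the local workflow's "
                f"budget of {cfg.memory_budget}; use the server workflow"
            )

        # ---- preprocess ---------------------------------------------------
        states = _stage("preprocess")(
            lambda: [
                discretize_events(apply_oob_filter(t, panel), panel) for t in tables
            ]
        )()
        n_cells = int(sum(s.n_cells for s in states))
        manifest["tallies"]["samples"] = len(states)
        manifest["tallies"]["cells_after_oob"] = n_cells
        log.info("preprocess: %d samples, %d cells retained", len(states), n_cells)

        # ---- combinatorics ------------------------------------------------
        def _count():
            full = count_full_length(states, panel)
            return full, expand_neutral(
                full, counting, n_workers=cfg.threads, out_dir=out / "counts"
            )

        full, counts_manifest = _stage("combinatorics")(_count)()
        manifest["tallies"]["full_length_phenotypes"] = int(full.n_phenotypes)
        manifest["tallies"]["phenotypes"] = int(counts_manifest.n_phenotypes)
        log.info(
            "combinatorics: %d full-length phenotypes, %d phenotypes after "
            "expansion and filtering",
            full.n_phenotypes, counts_manifest.n_phenotypes,
        )

        # ---- stats --------------------------------------------------------
        def _stats() -> pd.DataFrame:
            denominators = None
            if parent is not None:
                prow = find_phenotypes_in_files(
                    counts_manifest, [parent.render(panel)]
                )
                if prow.n_phenotypes == 0:
                    raise ConfigurationError(
                        "parent phenotype was filtered out of the count table"
                    )
                denominators = prow.counts[0]
            if cfg.workflow == "local":
                table = counts_manifest.load_table()
                return evaluate_phenotypes(
                    table, annotation, mode, denominators=denominators
                )
            # server: chunkwise; first pass pins the global pseudocount
            eps = None
            if mode == "group":
                smallest = np.inf
                denom = (
                    denominators
                    if denominators is not None
                    else counts_manifest.sample_totals
                ).astype(float)
                for chunk in counts_manifest.iter_tables():
                    freq = chunk.counts[:, denom > 0] / denom[denom > 0]
                    nz = freq[freq > 0]
                    if nz.size:
                        smallest = min(smallest, float(nz.min()))
                eps = smallest / 2.0 if np.isfinite(smallest) else 0.5
            parts = [
                evaluate_phenotypes(
                    chunk, annotation, mode, denominators=denominators, eps=eps
                )
                for chunk in counts_manifest.iter_tables()
            ]
            joined = pd.concat(parts, ignore_index=True) if parts else parts
            joined.attrs = dict(parts[0].attrs) if parts else {}
            return joined

        stats = _stage("stats")(_stats)()
        stats.to_csv(out / "stats.tsv", sep="\t", index=False)
        significant = filter_significant(stats, cfg.p_threshold)
        manifest["tallies"]["tested_phenotypes"] = int(len(stats))
        manifest["tallies"]["significant_phenotypes"] = int(len(significant))
        log.info(
            "stats (%s mode): %d phenotypes tested, %d at p <= %g",
            mode, len(stats), len(significant), cfg.p_threshold,
        )

        # ---- independence -------------------------------------------------
        def _independent() -> pd.DataFrame:
            icfg = IndependenceConfig(
                n_subnetworks=cfg.n_subnetworks,
                community_seed=cfg.community_seed,
                ranking_mode=mode,
                match_states=cfg.match_states,
                max_network_size=cfg.max_network_size,
            )
            node_states = decode_codes(significant["code"].to_numpy(), panel)
            return find_independent_phenotypes(significant, node_states, icfg)

        report = _stage("independence")(_independent)()
        report.to_csv(out / "independent.tsv", sep="\t", index=False)
        n_conf1 = int((report["confidence"] == 1.0).sum()) if len(report) else 0
        manifest["tallies"]["representatives_confidence_1"] = n_conf1
        log.info(
            "independence: %d candidate phenotypes, %d at confidence 1.0",
            len(report), n_conf1,
        )

        manifest["complete"] = True
        return out
    finally:
        save_manifest()
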