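"""Synthetic cytometry cohorts with known ground truth.

Two generators:

* **worst case** — every full-length phenotype present in every sample with
  a near-equal number of cells.  This is the hardest input for combinatorial
  counting (real panels are far sparser, since biology forbids most marker
  co-expression patterns), and is used for counting benchmarks and oracle
  tests.
* **planted cohort** — a two-group cohort sharing one fixed multinomial over
  full-length phenotypes, with the mass of every full-length phenotype
  refining a chosen *planted* phenotype multiplied by ``effect`` in group 2
  (then renormalized).  The attenuated expected fold change of the planted
  phenotype is closed-form: ``effect / (1 + (effect - 1) * f)`` with ``f``
  the planted phenotype's baseline mass.  Optionally, exponential event times
  with log-hazard proportional to the planted phenotype's frequency.

Intensities are drawn uniformly inside unit-width state intervals with
thresholds on the integer grid, so discretization recovers the generating
states exactly.  The generators emulate gated, compensated data; they do not
model spillover, acquisition drift or batch effects.  Same seed, same bytes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    ConfigurationError,
    EventTable,
    MarkerDef,
    MarkerPanel,
    write_panel_csv,
)

__all__ = [
    "PlantedEffect",
    "SurvivalModel",
    "SynthConfig",
    "make_panel",
    "generate_worst_case",
    "generate_planted_cohort",
    "save_cohort",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class PlantedEffect:
    """A phenotype whose frequency differs between groups.

    ``phenotype`` is a per-marker state vector (0 = neutral); ``effect``
    multiplies the multinomial mass of its full-length refinements in group 2
    (< 1 down-weights, must be > 0); ``group_sizes`` are samples per group.
    """

    phenotype: tuple[int, ...]
    group_sizes: tuple[int, int] = (20, 20)
    effect: float = 4.0

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ConfigurationError("planted effect must be > 0")
        if not any(self.phenotype):
            raise ConfigurationError("planted phenotype must have length >= 1")


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential event times: hazard = baseline_rate * exp(beta * freq)."""

    beta: float = 1.0
    baseline_rate: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Cohort geometry and ground truth.

    Defaults describe the standard validation cohort: 8 two-state markers,
    20 000 cells per sample, 20 + 20 samples, planted phenotype A+B+ with a
    four-fold group-2 enrichment.
    """

    m: int = 8
    n: int = 2
    cells_per_sample: int = 20_000
    n_samples: int = 40
    seed: int = 0
    planted: PlantedEffect | None = field(
        default_factory=lambda: PlantedEffect(phenotype=(2, 2, 0, 0, 0, 0, 0, 0))
    )
    survival: SurvivalModel | None = None


def make_panel(m: int, n: int = 2, oob_limit: float | None = None) -> MarkerPanel:
    """Panel of ``m`` markers, ``n`` states each, thresholds at 1..n-1."""
    if m < 1 or n < 2:
        raise ConfigurationError("need m >= 1 markers with n >= 2 states")
    names = (
        list(_LETTERS[:m]) if m <= 26 else [f"M{i:02d}" for i in range(1, m + 1)]
    )
    return MarkerPanel(
        tuple(
            MarkerDef(name, tuple(float(t) for t in range(1, n)), oob_limit=oob_limit)
            for name in names
        )
    )


def _full_state_vectors(m: int, n: int) -> np.ndarray:
    """All n^m full-length state vectors, ascending mixed-radix code order."""
    return np.array(
        list(itertools.product(range(1, n + 1), repeat=m)), dtype=np.int64
    )


def _sample_ids(n_samples: int) -> list[str]:
    width = max(2, len(str(n_samples)))
    return [f"s{i:0{width}d}" for i in range(1, n_samples + 1)]


def _events_from_counts(
    rng: np.random.Generator,
    counts: np.ndarray,
    full_states: np.ndarray,
    panel: MarkerPanel,
    sample_id: str,
) -> EventTable:
    states = np.repeat(full_states, counts, axis=0)
    values = states - 1.0 + rng.random(states.shape)
    return EventTable(sample_id, pd.DataFrame(values, columns=panel.names))


def generate_worst_case(cfg: SynthConfig) -> tuple[list[EventTable], MarkerPanel]:
    """Every full-length phenotype in every sample, counts differing by <= 1.

    ``cells_per_sample`` must be at least ``n^m`` so each of the ``n^m``
    full-length phenotypes is representable; the integer-division remainder is
    spread over a random (seeded) subset of phenotypes.
    """
    n_full = cfg.n ** cfg.m
    if cfg.cells_per_sample < n_full:
        raise ConfigurationError(
            f"worst case needs cells_per_sample >= n^m = {n_full}"
        )
    rng = np.random.default_rng(cfg.seed)
    panel = make_panel(cfg.m, cfg.n)
    full_states = _full_state_vectors(cfg.m, cfg.n)
    base, rem = divmod(cfg.cells_per_sample, n_full)
    tables = []
    for sid in _sample_ids(cfg.n_samples):
        counts = np.full(n_full, base, dtype=np.int64)
        if rem:
            counts[rng.choice(n_full, size=rem, replace=False)] += 1
        tables.append(_events_from_counts(rng, counts, full_states, panel, sid))
    return tables, panel


def _refinement_mask(full_states: np.ndarray, phenotype: Sequence[int]) -> np.ndarray:
    idx = [i for i, s in enumerate(phenotype) if s != 0]
    vals = [phenotype[i] for i in idx]
    return (full_states[:, idx] == vals).all(axis=1)


def generate_planted_cohort(
    cfg: SynthConfig,
) -> tuple[list[EventTable], MarkerPanel, pd.DataFrame, dict]:
    """Two-group cohort with a multiplicative planted frequency shift.

    The background multinomial over full-length phenotypes is drawn once per
    cohort from a symmetric Dirichlet (concentration 5 — moderately uneven,
    as real gated subsets are) and shared by both groups; group 2 reweights
    the planted phenotype's refinements by ``effect``.  ``effect = 1``
    reduces exactly to the null generator.  Returns the event tables, the
    panel, the sample annotation and a manifest recording the generator's
    parameters and the closed-form expected log2 fold change.
    """
    if cfg.planted is None:
        raise ConfigurationError("planted cohort needs cfg.planted")
    planted = cfg.planted
    if len(planted.phenotype) != cfg.m:
        raise ConfigurationError("planted phenotype length != number of markers")
    g1, g2 = planted.group_sizes
    n_samples = g1 + g2
    rng = np.random.default_rng(cfg.seed)
    panel = make_panel(cfg.m, cfg.n)
    n_full = cfg.n ** cfg.m
    full_states = _full_state_vectors(cfg.m, cfg.n)

    base = rng.dirichlet(np.full(n_full, 5.0))
    mask = _refinement_mask(full_states, planted.phenotype)
    w2 = base * np.where(mask, planted.effect, 1.0)
    w2 = w2 / w2.sum()

    ids = _sample_ids(n_samples)
    groups = ["g1"] * g1 + ["g2"] * g2
    tables = []
    planted_freq = np.empty(n_samples)
    for j, (sid, grp) in enumerate(zip(ids, groups)):
        w = base if grp == "g1" else w2
        counts = rng.multinomial(cfg.cells_per_sample, w)
        planted_freq[j] = counts[mask].sum() / cfg.cells_per_sample
        tables.append(_events_from_counts(rng, counts, full_states, panel, sid))

    annotation = pd.DataFrame({"sample_id": ids, "group": groups})
    if cfg.survival is not None:
        hazard = cfg.survival.baseline_rate * np.exp(
            cfg.survival.beta * planted_freq
        )
        annotation["time"] = rng.exponential(1.0 / hazard)
        annotation["event"] = 1

    f = float(base[mask].sum())
    expected_fc = planted.effect / (1.0 + (planted.effect - 1.0) * f)
    manifest = {
        "m": cfg.m,
        "n": cfg.n,
        "cells_per_sample": cfg.cells_per_sample,
        "seed": cfg.seed,
        "planted_phenotype": list(planted.phenotype),
        "group_sizes": [g1, g2],
        "effect": planted.effect,
        "planted_base_mass": f,
        "expected_log2_fold_change": math.log2(expected_fc),
        "survival": None
        if cfg.survival is None
        else {"beta": cfg.survival.beta, "baseline_rate": cfg.survival.baseline_rate},
    }
    return tables, panel, annotation, manifest


def save_cohort(
    out_dir: str | Path,
    tables: Sequence[EventTable],
    panel: MarkerPanel,
    annotation: pd.DataFrame | None = None,
    fmt: str = "csv",
) -> dict[str, Path]:
    """Write event files (CSV or FCS), the gating-threshold CSV and annotation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t in tables:
        if fmt == "fcs":
            from .preprocess import write_fcs

            p = out / f"{t.sample_id}.fcs"
            write_fcs(t, p)
        else:
            p = out / f"{t.sample_id}.csv"
            t.values.to_csv(p, index=False)
        paths[t.sample_id] = p
    write_panel_csv(panel, out / "gating.csv")
    paths["gating"] = out / "gating.csv"
    if annotation is not None:
        annotation.to_csv(out / "annotation.csv", index=False)
        paths["annotation"] = out / "annotation.csv"
    return paths
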