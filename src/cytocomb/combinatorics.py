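"""Combinatorial phenotype enumeration and memory-safe cell counting.

A *phenotype* assigns to each of the ``m`` panel markers either a concrete
state (``1..n_k``) or the neutral state ``0`` (marker unconstrained).  With
``n_k`` states per marker there are ``prod(n_k + 1) - 1`` phenotypes (the
all-neutral assignment is excluded).  Each phenotype is identified by its
mixed-radix integer code with base ``n_k + 1`` per marker, which is compact,
bijective and gives a canonical ascending ordering.

Counting proceeds the way the combinatorial explosion demands: cells are first
aggregated into the full-length phenotypes actually present in the data (at
most ``min(total cells, prod n_k)`` of them), then every neutral-state
phenotype is obtained by marginalizing those counts over the neutralized
markers.  Each marginalization is independent, so they can run concurrently
and stream to disk in bounded-size chunks.
"""

from __future__ import annotations

import gzip
import itertools
import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .preprocess import ConfigurationError, DataError, MarkerPanel, StateMatrix

__all__ = [
    "PhenotypeCode",
    "CountTable",
    "CountingConfig",
    "ChunkManifest",
    "total_phenotype_count",
    "projected_phenotype_count",
    "place_values",
    "encode_states",
    "decode_codes",
    "render_phenotype",
    "parse_phenotype",
    "count_full_length",
    "expand_neutral",
    "filter_by_parent",
    "find_phenotypes_in_files",
]


# ---------------------------------------------------------------------------
# Phenotype codes
# ---------------------------------------------------------------------------

def place_values(panel: MarkerPanel) -> np.ndarray:
    """Mixed-radix place value of each marker (last marker is least significant)."""
    radices = panel.radices
    total = math.prod(int(r) for r in radices)
    if total - 1 > np.iinfo(np.int64).max:
        raise ConfigurationError(
            f"panel of {len(panel)} markers overflows 64-bit phenotype codes; "
            "restrict the panel or analyze per parent lineage"
        )
    places = np.ones(len(radices), dtype=np.int64)
    places[:-1] = np.cumprod(radices[::-1])[-2::-1]
    return places


def total_phenotype_count(panel: MarkerPanel) -> int:
    """Total number of phenotypes: ``prod(n_k + 1) - 1`` (all-neutral excluded)."""
    return math.prod(int(r) for r in panel.radices) - 1


def projected_phenotype_count(panel: MarkerPanel, max_length: int) -> int:
    """Upper bound on phenotypes of length ``1..max_length``.

    Coefficient sum of ``prod_k (1 + n_k x)`` for degrees 1..max_length;
    equals ``total_phenotype_count`` when ``max_length == m``.
    """
    poly = [1]
    for n in panel.n_states:
        nxt = [0] * (len(poly) + 1)
        for d, c in enumerate(poly):
            nxt[d] += c
            nxt[d + 1] += c * int(n)
        poly = nxt
    return sum(poly[1 : max_length + 1])


def encode_states(states: np.ndarray, panel: MarkerPanel) -> np.ndarray:
    """Mixed-radix encode state vectors (rows) to integer codes."""
    states = np.asarray(states, dtype=np.int64)
    radices = panel.radices
    if states.size and ((states < 0) | (states >= radices)).any():
        raise ConfigurationError("state out of range for its marker")
    return states @ place_values(panel)


def decode_codes(codes: np.ndarray, panel: MarkerPanel) -> np.ndarray:
    """Invert :func:`encode_states`; returns (len(codes), m) state matrix."""
    codes = np.asarray(codes, dtype=np.int64)
    places = place_values(panel)
    out = np.empty((len(codes), len(panel)), dtype=np.int64)
    rem = codes
    for k, p in enumerate(places):
        out[:, k], rem = np.divmod(rem, p)
    return out


@dataclass(frozen=True)
class PhenotypeCode:
    """A phenotype as a per-marker state vector; 0 marks a neutral marker."""

    states: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))
        if self.length < 1:
            raise ConfigurationError("the all-neutral phenotype is not a phenotype")

    @property
    def length(self) -> int:
        """Number of non-neutral markers (phenotype length, ``l``)."""
        return sum(1 for s in self.states if s != 0)

    def code(self, panel: MarkerPanel) -> int:
        return int(encode_states(np.array([self.states]), panel)[0])

    def render(self, panel: MarkerPanel) -> str:
        return render_phenotype(self.states, panel)

    def refines(self, parent: "PhenotypeCode") -> bool:
        """True if this phenotype agrees with every non-neutral parent marker."""
        return all(p == 0 or s == p for s, p in zip(self.states, parent.states))


def render_phenotype(states: Sequence[int], panel: MarkerPanel) -> str:
    """Canonical string: non-neutral markers in panel order, name + state label."""
    parts = []
    for s, m in zip(states, panel):
        if s:
            parts.append(m.name + m.state_labels[s - 1])
    if not parts:
        raise ConfigurationError("cannot render the all-neutral phenotype")
    return "".join(parts)


def parse_phenotype(text: str, panel: MarkerPanel) -> PhenotypeCode:
    """Parse a phenotype string (any marker order) to its canonical code.

    Marker names are matched greedily (longest first), then the longest state
    label of that marker; a Unicode minus is accepted for ``-``.
    """
    s = text.replace("−", "-").strip()
    by_len = sorted(range(len(panel)), key=lambda i: -len(panel.names[i]))
    states = [0] * len(panel)
    pos = 0
    while pos < len(s):
        for i in by_len:
            name = panel.names[i]
            if s.startswith(name, pos):
                rest = pos + len(name)
                labels = sorted(
                    enumerate(panel.markers[i].state_labels),
                    key=lambda t: -len(t[1]),
                )
                for j, lab in labels:
                    if lab and s.startswith(lab, rest):
                        if states[i] not in (0, j + 1):
                            raise DataError(
                                f"phenotype {text!r}: conflicting states for {name}"
                            )
                        states[i] = j + 1
                        pos = rest + len(lab)
                        break
                else:
                    raise DataError(
                        f"phenotype {text!r}: no state label after marker {name!r}"
                    )
                break
        else:
            raise DataError(f"phenotype {text!r}: unparseable at {s[pos:]!r}")
    return PhenotypeCode(tuple(states))


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Phenotype-by-sample cell counts.

    ``codes`` are mixed-radix phenotype codes (canonical ascending order for
    tables produced by this module); ``counts`` is the aligned
    (phenotype, sample) integer matrix.  ``sample_totals`` records the number
    of cells per sample after preprocessing (the frequency denominator when no
    parent is set); ``parent`` is the phenotype the table was conditioned on,
    if any.
    """

    panel: MarkerPanel
    codes: np.ndarray
    samples: list[str]
    counts: np.ndarray
    sample_totals: np.ndarray
    parent: PhenotypeCode | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.sample_totals = np.asarray(self.sample_totals, dtype=np.int64)
        if self.counts.shape != (len(self.codes), len(self.samples)):
            raise ConfigurationError("counts shape does not match codes x samples")
        if self.counts.size and self.counts.min() < 0:
            raise ConfigurationError("negative cell count")

    @property
    def n_phenotypes(self) -> int:
        return len(self.codes)

    def states(self) -> np.ndarray:
        return decode_codes(self.codes, self.panel)

    def lengths(self) -> np.ndarray:
        return (self.states() != 0).sum(axis=1)

    def strings(self) -> list[str]:
        return [render_phenotype(s, self.panel) for s in self.states()]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "phenotype", self.strings())
        df.insert(0, "code", self.codes)
        return df

    def row(self, phenotype: PhenotypeCode) -> np.ndarray:
        code = phenotype.code(self.panel)
        idx = np.nonzero(self.codes == code)[0]
        if not len(idx):
            raise KeyError(phenotype.render(self.panel))
        return self.counts[idx[0]]

    def sorted_by_code(self) -> "CountTable":
        order = np.argsort(self.codes, kind="stable")
        return replace(self, codes=self.codes[order], counts=self.counts[order])


@dataclass(frozen=True)
class CountingConfig:
    """Filters and resource knobs for neutral-state expansion.

    ``max_length`` caps phenotype complexity; a phenotype is kept only when it
    has at least ``min_count`` cells in at least ``min_sample_fraction`` of
    samples (inclusive comparisons on both); ``parent`` restricts output to
    refinements of one phenotype; ``chunk_size`` is the number of phenotype
    rows per on-disk chunk in the server workflow.
    """

    max_length: int
    min_count: int = 0
    min_sample_fraction: float = 0.0
    parent: PhenotypeCode | None = None
    chunk_size: int = 100_000

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ConfigurationError("max_length must be >= 1")
        if not 0.0 <= self.min_sample_fraction <= 1.0:
            raise ConfigurationError("min_sample_fraction must be in [0, 1]")
        if self.min_count < 0:
            raise ConfigurationError("min_count must be >= 0")
        if self.chunk_size < 1:
            raise ConfigurationError("chunk_size must be >= 1")


def count_full_length(
    state_matrices: Sequence[StateMatrix], panel: MarkerPanel
) -> CountTable:
    """Count cells per full-length phenotype (length = m) per sample.

    Only phenotypes observed in at least one sample are materialized; samples
    with zero cells contribute an all-zero column.
    """
    samples = [sm.sample_id for sm in state_matrices]
    if len(set(samples)) != len(samples):
        raise ConfigurationError("duplicate sample ids")
    places = place_values(panel)
    per_sample_codes = []
    for sm in state_matrices:
        if sm.states.shape[1] != len(panel):
            raise ConfigurationError(
                f"sample {sm.sample_id!r}: {sm.states.shape[1]} state columns "
                f"for a {len(panel)}-marker panel"
            )
        per_sample_codes.append(np.asarray(sm.states, dtype=np.int64) @ places)
    all_codes = (
        np.unique(np.concatenate(per_sample_codes))
        if per_sample_codes and sum(map(len, per_sample_codes))
        else np.empty(0, dtype=np.int64)
    )
    counts = np.zeros((len(all_codes), len(samples)), dtype=np.int64)
    for j, codes in enumerate(per_sample_codes):
        if len(codes):
            idx = np.searchsorted(all_codes, codes)
            np.add.at(counts[:, j], idx, 1)
    totals = np.array([sm.n_cells for sm in state_matrices], dtype=np.int64)
    return CountTable(panel, all_codes, samples, counts, totals)


# ---------------------------------------------------------------------------
# Neutral-state expansion
# ---------------------------------------------------------------------------

def _marginalize(
    full_states: np.ndarray,
    full_counts: np.ndarray,
    kept: tuple[int, ...],
    places: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum full-length counts over every marker not in ``kept``."""
    child_codes = full_states[:, kept] @ places[list(kept)]
    uniq, inv = np.unique(child_codes, return_inverse=True)
    out = np.zeros((len(uniq), full_counts.shape[1]), dtype=np.int64)
    np.add.at(out, inv, full_counts)
    return uniq, out


def _iter_masks(
    m: int, cfg: CountingConfig
) -> Iterator[tuple[int, ...]]:
    """Deterministic order: by phenotype length, then lexicographic marker sets."""
    required: tuple[int, ...] = ()
    if cfg.parent is not None:
        required = tuple(i for i, s in enumerate(cfg.parent.states) if s != 0)
    free = [i for i in range(m) if i not in required]
    for length in range(max(1, len(required)), cfg.max_length + 1):
        for extra in itertools.combinations(free, length - len(required)):
            yield tuple(sorted(required + extra))


def _passes_filter(counts: np.ndarray, cfg: CountingConfig) -> np.ndarray:
    frac = (counts >= cfg.min_count).mean(axis=1) if counts.shape[1] else 0.0
    return np.asarray(frac >= cfg.min_sample_fraction)


def expand_neutral(
    full: CountTable,
    cfg: CountingConfig,
    *,
    n_workers: int = 1,
    out_dir: str | Path | None = None,
) -> "CountTable | ChunkManifest":
    """Generate all neutral-state phenotypes by marginal sums over full counts.

    Every phenotype of length ``1..max_length`` (refining ``cfg.parent`` when
    set) gets, per sample, the sum of the full-length counts consistent with
    it; rows failing the min-count/sample-fraction filter are dropped.  With
    ``out_dir`` set, rows stream to gzip text chunks of ``cfg.chunk_size``
    phenotypes plus a JSON manifest, and peak memory is bounded by the largest
    single marginalization, not by the output size.
    """
    panel = full.panel
    if cfg.max_length > len(panel):
        raise ConfigurationError("max_length exceeds the number of markers")
    places = place_values(panel)
    full_states = full.states()
    full_counts = full.counts
    if cfg.parent is not None:
        pidx = [i for i, s in enumerate(cfg.parent.states) if s != 0]
        pstates = [cfg.parent.states[i] for i in pidx]
        keep = (full_states[:, pidx] == pstates).all(axis=1)
        full_states, full_counts = full_states[keep], full_counts[keep]
        zero = full_counts.sum(axis=0) == 0
        if zero.any():
            import logging

            logging.getLogger("cytocomb").warning(
                "parent %s has zero cells in samples %s; frequencies undefined there",
                cfg.parent.render(panel),
                [s for s, z in zip(full.samples, zero) if z],
            )

    masks = list(_iter_masks(len(panel), cfg))
    writer = _ChunkWriter(out_dir, full, cfg) if out_dir is not None else None
    acc_codes: list[np.ndarray] = []
    acc_counts: list[np.ndarray] = []

    def run(kept: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        codes, counts = _marginalize(full_states, full_counts, kept, places)
        ok = _passes_filter(counts, cfg)
        return codes[ok], counts[ok]

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results: Iterable = pool.map(run, masks)
            for codes, counts in results:
                if writer is not None:
                    writer.append(codes, counts)
                else:
                    acc_codes.append(codes)
                    acc_counts.append(counts)
    else:
        for kept in masks:
            codes, counts = run(kept)
            if writer is not None:
                writer.append(codes, counts)
            else:
                acc_codes.append(codes)
                acc_counts.append(counts)

    if writer is not None:
        return writer.finalize()
    codes = (
        np.concatenate(acc_codes) if acc_codes else np.empty(0, dtype=np.int64)
    )
    counts = (
        np.concatenate(acc_counts)
        if acc_counts
        else np.empty((0, len(full.samples)), dtype=np.int64)
    )
    table = CountTable(
        panel, codes, full.samples, counts, full.sample_totals, parent=cfg.parent
    )
    return table.sorted_by_code()


def filter_by_parent(table: CountTable, parent: PhenotypeCode) -> CountTable:
    """Keep phenotypes agreeing with every non-neutral parent marker.

    The parent itself survives (it refines itself); its markers stay part of
    each child's definition.  The parent must be present in the table.
    """
    if parent.code(table.panel) not in set(table.codes.tolist()):
        raise ConfigurationError(
            f"parent {parent.render(table.panel)} not present in the table"
        )
    states = table.states()
    pidx = [i for i, s in enumerate(parent.states) if s != 0]
    pstates = [parent.states[i] for i in pidx]
    keep = (states[:, pidx] == pstates).all(axis=1)
    return replace(
        table, codes=table.codes[keep], counts=table.counts[keep], parent=parent
    )


# ---------------------------------------------------------------------------
# Chunked on-disk representation (server workflow)
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


@dataclass
class ChunkManifest:
    """Sidecar describing a directory of gzip count chunks."""

    directory: Path
    panel: MarkerPanel
    samples: list[str]
    sample_totals: np.ndarray
    chunks: list[str]
    n_phenotypes: int
    config: dict
    parent: PhenotypeCode | None = None

    def to_json(self) -> dict:
        return {
            "format": "cytocomb-counts/1",
            "panel": self.panel.to_dict(),
            "samples": list(self.samples),
            "sample_totals": [int(x) for x in self.sample_totals],
            "chunks": list(self.chunks),
            "n_phenotypes": int(self.n_phenotypes),
            "config": self.config,
            "parent": list(self.parent.states) if self.parent else None,
        }

    def save(self) -> Path:
        path = self.directory / MANIFEST_NAME
        path.write_text(json.dumps(self.to_json(), indent=1))
        return path

    @classmethod
    def load(cls, directory: str | Path) -> "ChunkManifest":
        directory = Path(directory)
        d = json.loads((directory / MANIFEST_NAME).read_text())
        return cls(
            directory=directory,
            panel=MarkerPanel.from_dict(d["panel"]),
            samples=d["samples"],
            sample_totals=np.array(d["sample_totals"], dtype=np.int64),
            chunks=d["chunks"],
            n_phenotypes=d["n_phenotypes"],
            config=d["config"],
            parent=PhenotypeCode(tuple(d["parent"])) if d["parent"] else None,
        )

    def chunk_paths(self) -> list[Path]:
        return [self.directory / c for c in self.chunks]

    def iter_tables(self) -> Iterator[CountTable]:
        """One in-memory :class:`CountTable` per chunk file."""
        for path in self.chunk_paths():
            yield _read_chunk(path, self)

    def load_table(self) -> CountTable:
        """Materialize every chunk (local-scale convenience)."""
        tables = list(self.iter_tables())
        codes = np.concatenate([t.codes for t in tables]) if tables else np.empty(0, np.int64)
        counts = (
            np.concatenate([t.counts for t in tables])
            if tables
            else np.empty((0, len(self.samples)), np.int64)
        )
        return CountTable(
            self.panel, codes, list(self.samples), counts, self.sample_totals,
            parent=self.parent,
        )


class _ChunkWriter:
    def __init__(self, out_dir: str | Path, full: CountTable, cfg: CountingConfig):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.full = full
        self.cfg = cfg
        self.buf_codes: list[np.ndarray] = []
        self.buf_counts: list[np.ndarray] = []
        self.buffered = 0
        self.chunks: list[str] = []
        self.total = 0

    def append(self, codes: np.ndarray, counts: np.ndarray) -> None:
        order = np.argsort(codes, kind="stable")
        self.buf_codes.append(codes[order])
        self.buf_counts.append(counts[order])
        self.buffered += len(codes)
        while self.buffered >= self.cfg.chunk_size:
            self._flush(self.cfg.chunk_size)

    def _flush(self, n: int) -> None:
        if not self.buffered:
            return
        codes = np.concatenate(self.buf_codes)
        counts = np.concatenate(self.buf_counts)
        take = min(n, len(codes))
        name = f"chunk_{len(self.chunks):05d}.tsv.gz"
        _write_chunk(self.dir / name, codes[:take], counts[:take], self.full.panel)
        self.chunks.append(name)
        self.total += take
        self.buf_codes = [codes[take:]]
        self.buf_counts = [counts[take:]]
        self.buffered = len(codes) - take

    def finalize(self) -> ChunkManifest:
        while self.buffered:
            self._flush(self.cfg.chunk_size)
        manifest = ChunkManifest(
            directory=self.dir,
            panel=self.full.panel,
            samples=list(self.full.samples),
            sample_totals=self.full.sample_totals,
            chunks=self.chunks,
            n_phenotypes=self.total,
            config={
                "max_length": self.cfg.max_length,
                "min_count": self.cfg.min_count,
                "min_sample_fraction": self.cfg.min_sample_fraction,
                "chunk_size": self.cfg.chunk_size,
            },
            parent=self.cfg.parent,
        )
        manifest.save()
        return manifest


def _write_chunk(
    path: Path, codes: np.ndarray, counts: np.ndarray, panel: MarkerPanel
) -> None:
    states = decode_codes(codes, panel)
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        for code, svec, row in zip(codes, states, counts):
            fh.write(
                f"{code}\t{render_phenotype(svec, panel)}\t"
                + "\t".join(str(int(c)) for c in row)
                + "\n"
            )


def _read_chunk(path: Path, manifest: ChunkManifest) -> CountTable:
    codes, rows = [], []
    with gzip.open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            codes.append(int(parts[0]))
            rows.append([int(x) for x in parts[2:]])
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.empty((0, len(manifest.samples)), dtype=np.int64)
    )
    return CountTable(
        manifest.panel,
        np.array(codes, dtype=np.int64),
        list(manifest.samples),
        counts,
        manifest.sample_totals,
        parent=manifest.parent,
    )


def find_phenotypes_in_files(
    source: str | Path | ChunkManifest, queries: Sequence[str]
) -> CountTable:
    """Look up phenotypes by string in chunked count files.

    Queries may list markers in any order; they are canonicalized against the
    manifest's panel before matching.  Chunks are scanned one at a time, so
    memory stays bounded by a single chunk; absent queries simply return no
    row.
    """
    manifest = (
        source if isinstance(source, ChunkManifest) else ChunkManifest.load(source)
    )
    panel = manifest.panel
    wanted = {parse_phenotype(q, panel).code(panel) for q in queries}
    hit_codes: list[np.ndarray] = []
    hit_counts: list[np.ndarray] = []
    for table in manifest.iter_tables():
        mask = np.isin(table.codes, list(wanted))
        if mask.any():
            hit_codes.append(table.codes[mask])
            hit_counts.append(table.counts[mask])
    codes = np.concatenate(hit_codes) if hit_codes else np.empty(0, np.int64)
    counts = (
        np.concatenate(hit_counts)
        if hit_counts
        else np.empty((0, len(manifest.samples)), np.int64)
    )
    out = CountTable(
        panel, codes, list(manifest.samples), counts, manifest.sample_totals,
        parent=manifest.parent,
    )
    return out.sorted_by_code()
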