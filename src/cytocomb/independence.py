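"""Independent ("driver") phenotype identification.

Enumerated significant phenotypes are massively redundant: a phenotype, its
refinements and its marginals all count overlapping cells.  To reduce a
significant set to independent candidates, phenotypes are linked in a
weighted network by a phenotypic-similarity score

    ps(p_i, p_j) = l(p_i ∩ p_j) / (l(p_i) + l(p_j)),

where ``l`` is phenotype length and the intersection counts markers on which
both phenotypes specify the *same* non-neutral state (identical phenotypes
score 0.5, disjoint ones 0).  The network is then pruned at ``n`` increasing
thresholds ``t_i = i * max(S) / (n + 1)``, edges below each threshold dropped
(edges exactly at the threshold kept).  Louvain modularity clustering labels
each pruned sub-network, one representative is picked per cluster by a
normalized ranking statistic, and each phenotype's *confidence score* is the
fraction of the ``n`` sub-networks in which it was selected.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse

from .preprocess import ConfigurationError

log = logging.getLogger("cytocomb")

__all__ = [
    "IndependenceConfig",
    "phenotypic_similarity",
    "build_similarity_network",
    "pruning_schedule",
    "prune",
    "detect_communities",
    "ranking_values",
    "select_representatives",
    "find_independent_phenotypes",
]


@dataclass(frozen=True)
class IndependenceConfig:
    """Sub-network count, clustering seed and ranking mode.

    ``n_subnetworks`` is the number of pruning thresholds (``n``); confidence
    scores live on the grid ``{0, 1/n, ..., 1}``.  ``match_states=False``
    relaxes the similarity intersection to count shared marker *names*
    regardless of state.  ``max_network_size`` caps the node count: when more
    phenotypes pass the significance filter than that, only the top-ranked
    ones enter the network (raw p-values saturate at the exact-test floor on
    well-powered cohorts, so the ranking statistic — not p — is what can still
    order the candidates).
    """

    n_subnetworks: int = 10
    community_seed: int = 0
    ranking_mode: str = "group"
    match_states: bool = True
    max_network_size: int = 500

    def __post_init__(self) -> None:
        if self.n_subnetworks < 1:
            raise ConfigurationError("n_subnetworks must be >= 1")
        if self.ranking_mode not in {"group", "correlation", "survival"}:
            raise ConfigurationError(f"unknown ranking mode {self.ranking_mode!r}")
        if self.max_network_size < 1:
            raise ConfigurationError("max_network_size must be >= 1")


def phenotypic_similarity(
    states_i, states_j, match_states: bool = True
) -> float:
    """Similarity of two phenotypes: shared marker-states over summed lengths.

    With ``match_states`` (default) a marker contributes to the intersection
    only when both phenotypes give it the same non-neutral state — A+ and A−
    denote disjoint cell sets, so sharing the marker name alone is not
    similarity.  Bounded by 0.5 (identical phenotypes).
    """
    a = np.asarray(states_i, dtype=np.int64)
    b = np.asarray(states_j, dtype=np.int64)
    la = int((a != 0).sum())
    lb = int((b != 0).sum())
    if la < 1 or lb < 1:
        raise ConfigurationError("phenotypes must have length >= 1")
    if match_states:
        shared = int(((a == b) & (a != 0)).sum())
    else:
        shared = int(((a != 0) & (b != 0)).sum())
    return shared / (la + lb)


def build_similarity_network(
    states: np.ndarray, match_states: bool = True
) -> np.ndarray:
    """Pairwise similarity matrix S (symmetric, zero diagonal, no self-loops).

    Computed in row blocks so peak memory stays ~O(P * block * m).
    """
    states = np.asarray(states, dtype=np.int64)
    P, _ = states.shape
    if P < 1:
        raise ConfigurationError("need at least one phenotype")
    lengths = (states != 0).sum(axis=1)
    S = np.empty((P, P), dtype=np.float64)
    block = max(1, 2_000_000 // max(1, P))
    for lo in range(0, P, block):
        hi = min(lo + block, P)
        chunk = states[lo:hi]
        if match_states:
            eq = (chunk[:, None, :] == states[None, :, :]) & (chunk[:, None, :] != 0)
        else:
            eq = (chunk[:, None, :] != 0) & (states[None, :, :] != 0)
        S[lo:hi] = eq.sum(axis=2) / (lengths[lo:hi, None] + lengths[None, :])
    np.fill_diagonal(S, 0.0)
    return S


def pruning_schedule(S: np.ndarray, n: int) -> list[float]:
    """Thresholds ``t_i = i * max(S) / (n + 1)`` for ``i = 1..n``.

    Strictly increasing and never reaching ``max(S)``, so the strongest edge
    survives every sub-network.  An all-zero matrix yields an empty schedule
    with a warning (nothing to prune; every phenotype is already isolated).
    """
    mx = float(S.max(initial=0.0))
    if mx <= 0.0:
        log.warning("similarity matrix has no positive edges; empty pruning schedule")
        return []
    return [i * mx / (n + 1) for i in range(1, n + 1)]


def prune(S: np.ndarray, t: float) -> np.ndarray:
    """Zero out edges with weight strictly below ``t`` (>= t kept)."""
    if t < 0:
        raise ConfigurationError("pruning threshold must be >= 0")
    out = np.where(S >= t, S, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def detect_communities(S: np.ndarray, seed: int = 0) -> np.ndarray:
    """Louvain modularity communities on the weighted graph of S.

    Uses igraph's multilevel (Louvain) implementation at resolution 1.
    Every node is labeled; isolated nodes form singleton communities.  The
    seed pins igraph's random generator, making labels reproducible.
    Labels are renumbered so that community ids follow the smallest member
    index, independent of the detection order.
    """
    P = S.shape[0]
    upper = sparse.csr_matrix(np.triu(S, 1))
    ig.set_random_number_generator(random.Random(seed))
    g = ig.Graph.Weighted_Adjacency(upper, mode="upper", attr="weight")
    if g.vcount() < P:
        g.add_vertices(P - g.vcount())
    if g.ecount() == 0:
        return np.arange(P, dtype=np.int64)
    membership = np.asarray(
        g.community_multilevel(weights="weight").membership, dtype=np.int64
    )
    # canonical renumbering by smallest member
    order = {}
    labels = np.empty(P, dtype=np.int64)
    for i, c in enumerate(membership):
        if c not in order:
            order[c] = len(order)
        labels[i] = order[c]
    return labels


def _minmax(x: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a degenerate range maps everything to 1."""
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.ones_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def ranking_values(stats: pd.DataFrame, mode: str) -> np.ndarray:
    """Normalized ranking statistic over the selected phenotype set.

    group: |effect size| * |log2 fold change|, each factor min-max normalized
    over the set before multiplication; correlation: normalized |tau|;
    survival: normalized |Cox coefficient|.
    """
    if mode == "group":
        a = _minmax(np.abs(stats["effect_size"].to_numpy(dtype=float)))
        b = _minmax(np.abs(stats["log2_fold_change"].to_numpy(dtype=float)))
        return a * b
    if mode == "correlation":
        return _minmax(np.abs(stats["effect_size"].to_numpy(dtype=float)))
    if mode == "survival":
        return _minmax(np.abs(stats["statistic"].to_numpy(dtype=float)))
    raise ConfigurationError(f"unknown ranking mode {mode!r}")


def select_representatives(
    labels: np.ndarray,
    ranking: np.ndarray,
    lengths: np.ndarray,
    codes: np.ndarray,
) -> np.ndarray:
    """Index of the top-ranked phenotype per cluster.

    Ties on the ranking value are broken deterministically: shorter phenotype
    first, then smaller mixed-radix code.
    """
    reps = []
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        key = sorted(
            members,
            key=lambda i: (-ranking[i], lengths[i], codes[i]),
        )
        reps.append(key[0])
    return np.array(sorted(reps), dtype=np.int64)


def find_independent_phenotypes(
    stats: pd.DataFrame,
    states: np.ndarray,
    cfg: IndependenceConfig,
) -> pd.DataFrame:
    """Full deduplication pass: network, pruned sub-networks, confidence.

    ``stats`` holds one row per selected (significant) phenotype, aligned with
    ``states`` (per-marker state vectors).  Returns the representative report:
    phenotype, ranking value, confidence score, and per-threshold cluster
    label / representative flag columns.  With no positive similarity at all
    (including the single-phenotype case) every phenotype is trivially its own
    representative, at confidence 1.
    """
    P = len(stats)
    if P != states.shape[0]:
        raise ConfigurationError("stats and state vectors are misaligned")
    if P == 0:
        return pd.DataFrame(
            columns=["code", "phenotype", "length", "ranking", "confidence"]
        )
    if P > cfg.max_network_size:
        pre = ranking_values(stats, cfg.ranking_mode)
        top = np.argsort(-pre, kind="stable")[: cfg.max_network_size]
        top = np.sort(top)
        log.info(
            "independence network capped at the top %d of %d phenotypes by "
            "ranking statistic", cfg.max_network_size, P,
        )
        stats = stats.iloc[top].reset_index(drop=True)
        states = states[top]
        P = len(stats)
    ranking = ranking_values(stats, cfg.ranking_mode)
    lengths = (states != 0).sum(axis=1)
    codes = stats["code"].to_numpy()

    report = stats[["code", "phenotype", "length"]].copy().reset_index(drop=True)
    report["ranking"] = ranking

    S = build_similarity_network(states, match_states=cfg.match_states)
    schedule = pruning_schedule(S, cfg.n_subnetworks)
    if not schedule:
        # edgeless network: every phenotype its own cluster, always selected
        report["confidence"] = 1.0
        for i in range(1, cfg.n_subnetworks + 1):
            report[f"cluster_t{i}"] = np.arange(P)
            report[f"rep_t{i}"] = True
        report.attrs["thresholds"] = []
        return report

    selected = np.zeros(P, dtype=np.int64)
    for i, t in enumerate(schedule, start=1):
        pruned = prune(S, t)
        labels = detect_communities(pruned, seed=cfg.community_seed)
        reps = select_representatives(labels, ranking, lengths, codes)
        flag = np.zeros(P, dtype=bool)
        flag[reps] = True
        selected += flag
        report[f"cluster_t{i}"] = labels
        report[f"rep_t{i}"] = flag
    report["confidence"] = selected / cfg.n_subnetworks
    cols = ["code", "phenotype", "length", "ranking", "confidence"] + [
        c for c in report.columns
        if c.startswith("cluster_t") or c.startswith("rep_t")
    ]
    report = report[cols]
    report.attrs["thresholds"] = schedule
    return report.sort_values(
        ["confidence", "ranking"], ascending=False, kind="stable"
    ).reset_index(drop=True)
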