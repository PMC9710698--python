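"""Phenotype frequencies and per-phenotype statistical screening.

All tests run on *cell frequencies* — a phenotype's count divided by the
sample's total cell count, or by the parent phenotype's count when the table
is conditioned on a parent — because total cells vary across samples.

Three comparison modes are supported, one per study design:

``group``
    two-sample comparison by the Mann-Whitney U test (exact null distribution
    when both groups have <= 25 samples and the data are tie-free, normal
    approximation with tie correction otherwise); effect size is the
    rank-biserial correlation ``2 U / (n1 n2) - 1``.
``correlation``
    association with a continuous covariate by Kendall's tau-b.
``survival``
    time-to-event association by a Cox proportional-hazards model with the
    frequency as the sole covariate (Efron tie handling); the statistic is
    the fitted log-hazard coefficient.

P-values are reported raw: enumerated phenotypes are heavily interdependent
(a phenotype and its refinements count overlapping cells), so the usual
multiple-comparison corrections do not apply; downstream deduplication is the
job of the independence module.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .combinatorics import CountTable, PhenotypeCode
from .preprocess import ConfigurationError, DataError

log = logging.getLogger("cytocomb")

__all__ = [
    "read_annotation",
    "annotation_mode",
    "compute_frequencies",
    "group_test",
    "correlation_test",
    "survival_test",
    "evaluate_phenotypes",
    "filter_significant",
]

STAT_COLUMNS = [
    "code", "phenotype", "length", "p_value", "statistic",
    "effect_size", "log2_fold_change", "mean_freq_g1", "mean_freq_g2", "flag",
]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation CSV (sample_id + group/covariate/time,event)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ConfigurationError(f"annotation {path}: missing sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ConfigurationError(f"annotation {path}: duplicate sample ids")
    return df


def annotation_mode(annotation: pd.DataFrame) -> str:
    """Infer the comparison mode from which annotation columns are populated."""
    if {"time", "event"}.issubset(annotation.columns):
        return "survival"
    if "group" in annotation.columns:
        return "group"
    if "covariate" in annotation.columns:
        return "correlation"
    raise ConfigurationError(
        "annotation must provide group, covariate, or time+event columns"
    )


def compute_frequencies(
    table: CountTable, denominators: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-sample phenotype frequencies.

    Denominator is the sample's total cell count, or the parent phenotype's
    per-sample count when ``table.parent`` is set.  Samples with a zero
    denominator are excluded with a warning.  ``denominators`` overrides both
    (used when a parent row lives in another chunk of a chunked table).
    """
    if denominators is not None:
        denom = np.asarray(denominators, dtype=float)
    elif table.parent is not None:
        denom = table.row(table.parent).astype(float)
    else:
        denom = table.sample_totals.astype(float)
    ok = denom > 0
    if not ok.all():
        excluded = [s for s, o in zip(table.samples, ok) if not o]
        log.warning("excluding samples with zero denominator: %s", excluded)
    freq = table.counts[:, ok] / denom[ok]
    return pd.DataFrame(
        freq, index=table.codes, columns=[s for s, o in zip(table.samples, ok) if o]
    )


def _base_frame(table: CountTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "code": table.codes,
            "phenotype": table.strings(),
            "length": table.lengths(),
        }
    )


def _split_groups(
    freqs: pd.DataFrame, annotation: pd.DataFrame, group_order: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    ann = annotation.set_index("sample_id").loc[list(freqs.columns)]
    levels = list(pd.unique(ann["group"])) if group_order is None else list(group_order)
    if group_order is None:
        levels = sorted(levels)
    if len(levels) != 2:
        raise ConfigurationError(f"group mode needs exactly 2 levels, got {levels}")
    g1 = ann.index[ann["group"] == levels[0]]
    g2 = ann.index[ann["group"] == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ConfigurationError("each group needs at least 2 samples")
    return (
        freqs[g1].to_numpy(),
        freqs[g2].to_numpy(),
        (str(levels[0]), str(levels[1])),
    )


def group_test(
    table: CountTable,
    annotation: pd.DataFrame,
    group_order: Sequence[str] | None = None,
    denominators: np.ndarray | None = None,
    eps: float | None = None,
) -> pd.DataFrame:
    """Mann-Whitney U comparison of phenotype frequencies between two groups.

    ``group_order`` fixes which level is the reference (group 1); by default
    levels are taken in sorted order.  The log2 fold change is
    ``log2(mean_g2 / mean_g1)``; when either group mean is zero a pseudocount
    ``eps`` — half the smallest nonzero frequency in the whole table — is
    added to both means, so phenotypes absent from one group get a finite,
    comparable fold change without distorting nonzero ratios (``eps`` can be
    supplied for chunked tables, where "the whole table" spans chunks).
    """
    freqs = compute_frequencies(table, denominators)
    x1, x2, (lv1, lv2) = _split_groups(freqs, annotation, group_order)
    n1, n2 = x1.shape[1], x2.shape[1]
    if eps is None:
        nz = freqs.to_numpy()
        nz = nz[nz > 0]
        eps = float(nz.min()) / 2.0 if nz.size else 0.5

    out = _base_frame(table)
    p = np.empty(len(out))
    u = np.empty(len(out))
    exact_ok = n1 <= 25 and n2 <= 25
    for i in range(len(out)):
        a, b = x1[i], x2[i]
        ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
        method = "exact" if exact_ok and not ties else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u[i], p[i] = res.statistic, res.pvalue
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    zero = (m1 == 0) | (m2 == 0)
    add = np.where(zero, eps, 0.0)
    out["p_value"] = np.minimum(p, 1.0)
    out["statistic"] = u
    out["effect_size"] = 2.0 * u / (n1 * n2) - 1.0
    out["log2_fold_change"] = np.log2((m2 + add) / (m1 + add))
    out["mean_freq_g1"] = m1
    out["mean_freq_g2"] = m2
    out["flag"] = ""
    out.attrs["groups"] = (lv1, lv2)
    out.attrs["mode"] = "group"
    return out


def correlation_test(
    table: CountTable,
    annotation: pd.DataFrame,
    denominators: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kendall tau-b between phenotype frequency and a continuous covariate."""
    freqs = compute_frequencies(table, denominators)
    ann = annotation.set_index("sample_id").loc[list(freqs.columns)]
    cov = ann["covariate"].to_numpy(dtype=float)
    if len(cov) < 3:
        raise ConfigurationError("correlation mode needs >= 3 samples")
    out = _base_frame(table)
    tau = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    flags = [""] * len(out)
    x = freqs.to_numpy()
    const_cov = np.ptp(cov) == 0
    for i in range(len(out)):
        if const_cov or np.ptp(x[i]) == 0:
            flags[i] = "constant"
            continue
        res = sps.kendalltau(x[i], cov)
        tau[i], p[i] = res.statistic, res.pvalue
    n_skip = sum(1 for f in flags if f)
    if n_skip:
        log.warning("correlation_test: %d phenotype(s) skipped (constant input)", n_skip)
    out["p_value"] = p
    out["statistic"] = tau
    out["effect_size"] = tau
    out["log2_fold_change"] = np.nan
    out["mean_freq_g1"] = np.nan
    out["mean_freq_g2"] = np.nan
    out["flag"] = flags
    out.attrs["mode"] = "correlation"
    return out


def survival_test(
    table: CountTable,
    annotation: pd.DataFrame,
    denominators: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit per phenotype (frequency as sole covariate).

    The reported statistic is the fitted log-hazard coefficient and the
    p-value the Wald test.  Degenerate designs (zero-variance frequency) and
    non-converging fits are flagged, not fatal.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    freqs = compute_frequencies(table, denominators)
    ann = annotation.set_index("sample_id").loc[list(freqs.columns)]
    time = ann["time"].to_numpy(dtype=float)
    event = ann["event"].to_numpy(dtype=int)
    if (time <= 0).any():
        raise DataError("survival mode requires time > 0 for every sample")
    if event.sum() < 1:
        raise DataError("survival mode requires at least one event")

    out = _base_frame(table)
    coef = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    flags = [""] * len(out)
    x = freqs.to_numpy()
    for i in range(len(out)):
        if np.ptp(x[i]) == 0:
            flags[i] = "zero-variance"
            continue
        df = pd.DataFrame({"time": time, "event": event, "freq": x[i]})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            coef[i] = cph.params_["freq"]
            p[i] = cph.summary.loc["freq", "p"]
        except (ConvergenceError, Exception) as exc:  # noqa: BLE001
            flags[i] = f"fit-failed: {type(exc).__name__}"
    out["p_value"] = p
    out["statistic"] = coef
    out["effect_size"] = np.nan
    out["log2_fold_change"] = np.nan
    out["mean_freq_g1"] = np.nan
    out["mean_freq_g2"] = np.nan
    out["flag"] = flags
    out.attrs["mode"] = "survival"
    return out


def evaluate_phenotypes(
    table: CountTable,
    annotation: pd.DataFrame,
    mode: str | None = None,
    group_order: Sequence[str] | None = None,
    denominators: np.ndarray | None = None,
    eps: float | None = None,
) -> pd.DataFrame:
    """Dispatch to the test matching the annotation (or the explicit mode)."""
    mode = mode or annotation_mode(annotation)
    if mode == "group":
        return group_test(table, annotation, group_order, denominators, eps)
    if mode == "correlation":
        return correlation_test(table, annotation, denominators)
    if mode == "survival":
        return survival_test(table, annotation, denominators)
    raise ConfigurationError(f"unknown test mode {mode!r}")


def filter_significant(
    stats: pd.DataFrame,
    p_threshold: float,
    parent: PhenotypeCode | None = None,
    panel=None,
) -> pd.DataFrame:
    """Keep phenotypes with raw p <= threshold (no multiplicity adjustment).

    Enumerated phenotypes are not independent observations, so adjusted
    p-values are not meaningful here; significant sets should be read as
    discovery candidates.  An optional parent restricts the output to its
    refinements (``panel`` required to decode codes in that case).
    """
    keep = stats["p_value"].to_numpy() <= p_threshold
    out = stats.loc[keep].copy()
    if parent is not None:
        if panel is None:
            raise ConfigurationError("parent filtering needs the panel")
        from .combinatorics import decode_codes

        states = decode_codes(out["code"].to_numpy(), panel)
        pidx = [i for i, s in enumerate(parent.states) if s != 0]
        pstates = [parent.states[i] for i in pidx]
        mask = (states[:, pidx] == pstates).all(axis=1) if len(out) else np.array([], bool)
        out = out.loc[mask]
    out.attrs = dict(stats.attrs)
    return out.reset_index(drop=True)
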