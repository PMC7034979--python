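"""Discretized expression states, concordance statistics and marker genes.

Probabilities are discretized into ``on`` (P >= 0.8), ``off`` (P <= 0.2) and
``ambiguous`` in between. Concordance is quantified between replicate samples
of the same driver and against an external protein-expression benchmark.
Marker detection finds genes expressed in every member of a cell group, in at
most a couple of cells outside it, and at higher abundance inside than out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleMetadata

logger = logging.getLogger(__name__)

STATE_ON = "on"
STATE_OFF = "off"
STATE_AMBIGUOUS = "ambiguous"


@dataclass
class BenchmarkResult:
    """Concordance against curated (gene, cell type, expected state) points."""

    concordance: float
    matches: pd.DataFrame
    mismatches: pd.DataFrame
    ambiguous: pd.DataFrame
    unresolved: pd.DataFrame
    positive_probability_cdf: pd.DataFrame  # sorted P at positive points + ECDF


def discretize(
    probs: pd.DataFrame, on_cut: float = 0.8, off_cut: float = 0.2
) -> pd.DataFrame:
    """Threshold P(z=on) into on/off/ambiguous labels; NA propagates."""
    if not 0 <= off_cut < on_cut <= 1:
        raise ValueError("need 0 <= off_cut < on_cut <= 1")
    p = probs.to_numpy(dtype=float)
    out = np.where(p >= on_cut, STATE_ON, np.where(p <= off_cut, STATE_OFF, STATE_AMBIGUOUS))
    out = np.where(np.isnan(p), None, out)
    states = pd.DataFrame(out, index=probs.index, columns=probs.columns)
    states.attrs["on_cut"] = on_cut
    states.attrs["off_cut"] = off_cut
    return states


def replicate_concordance(
    sample_states: pd.DataFrame, metadata: SampleMetadata
) -> tuple[pd.Series, float]:
    """Fraction of genes with identical state labels across a driver's replicates.

    All three labels (on/off/ambiguous) count as distinct; genes with an NA
    call in any replicate are excluded for that driver. Drivers with a single
    sample carry no replicate information and are skipped. Returns the
    per-driver concordances and their median.
    """
    driver_of = metadata.driver_of()
    per_driver = {}
    for driver, samples in driver_of.groupby(driver_of).groups.items():
        cols = [s for s in samples if s in sample_states.columns]
        if len(cols) < 2:
            logger.info("driver %s has < 2 replicate columns; skipped", driver)
            continue
        block = sample_states[cols]
        complete = block.notna().all(axis=1)
        if not complete.any():
            continue
        block = block.loc[complete]
        agree = block.eq(block.iloc[:, 0], axis=0).all(axis=1)
        per_driver[driver] = float(agree.mean())
    if not per_driver:
        raise ValueError("no driver with >= 2 replicates")
    series = pd.Series(per_driver, name="concordance").sort_index()
    return series, float(series.median())


def benchmark_concordance(
    cell_states: pd.DataFrame,
    cell_probs: pd.DataFrame,
    benchmark: pd.DataFrame,
) -> BenchmarkResult:
    """Compare inferred cell-level states with a curated benchmark table.

    ``benchmark`` has columns gene, cell_type, expected_state (on/off).
    Pairs absent from the matrix are reported and excluded; pairs with an
    ambiguous model call are excluded from the concordance denominator and
    returned separately. Also returns the empirical CDF of inferred
    probabilities at the positive (expected on) benchmark points.
    """
    if benchmark.empty:
        raise ValueError("benchmark table is empty")
    bench = benchmark.copy()
    if bench.duplicated(["gene", "cell_type"]).any():
        raise ValueError("duplicate (gene, cell_type) pairs in benchmark")
    resolvable = bench["gene"].isin(cell_states.index) & bench["cell_type"].isin(
        cell_states.columns
    )
    unresolved = bench.loc[~resolvable]
    if len(unresolved):
        logger.info("%d benchmark points not resolvable in the matrix", len(unresolved))
    bench = bench.loc[resolvable].copy()
    idx = pd.MultiIndex.from_frame(bench[["gene", "cell_type"]])
    states_long = cell_states.stack(future_stack=True)
    probs_long = cell_probs.stack(future_stack=True)
    bench["called_state"] = states_long.reindex(idx).to_numpy()
    bench["probability"] = probs_long.reindex(idx).to_numpy()
    na = bench["called_state"].isna()
    ambiguous = bench.loc[(bench["called_state"] == STATE_AMBIGUOUS) | na]
    judged = bench.loc[(bench["called_state"] != STATE_AMBIGUOUS) & ~na]
    matches = judged.loc[judged["called_state"] == judged["expected_state"]]
    mismatches = judged.loc[judged["called_state"] != judged["expected_state"]]
    denom = len(matches) + len(mismatches)
    concordance = len(matches) / denom if denom else float("nan")
    positive = bench.loc[bench["expected_state"] == STATE_ON, "probability"].dropna().sort_values()
    cdf = pd.DataFrame(
        {
            "probability": positive.to_numpy(),
            "cdf": np.arange(1, len(positive) + 1) / max(len(positive), 1),
        }
    )
    return BenchmarkResult(
        concordance=float(concordance),
        matches=matches,
        mismatches=mismatches,
        ambiguous=ambiguous,
        unresolved=unresolved,
        positive_probability_cdf=cdf,
    )


def find_group_markers(
    cell_probs: pd.DataFrame,
    cell_abundance: pd.DataFrame,
    group: set[str] | list[str],
    in_cut: float = 0.9,
    max_outside: int = 2,
) -> pd.DataFrame:
    """Genes expressed in every cell of a group and almost nowhere else.

    Three criteria: P(z=on) >= ``in_cut`` in all group cells; at most
    ``max_outside`` non-group cells reach ``in_cut``; and the lowest mean
    abundance inside the group exceeds the highest outside. With
    ``group`` = all cells the outside conditions are vacuous and the rules
    reduce to "on everywhere".
    """
    group = sorted(set(group))
    if not group:
        raise ValueError("group must be non-empty")
    missing = [c for c in group if c not in cell_probs.columns]
    if missing:
        raise ValueError(f"group cells absent from matrix: {missing}")
    outside = [c for c in cell_probs.columns if c not in group]
    p_in = cell_probs[group].to_numpy()
    in_ok = (p_in >= in_cut).all(axis=1)
    if outside:
        p_out = cell_probs[outside].to_numpy()
        n_outside_on = np.nansum(p_out >= in_cut, axis=1)
        out_ok = n_outside_on <= max_outside
        min_in = cell_abundance[group].to_numpy().min(axis=1)
        max_out = cell_abundance[outside].to_numpy().max(axis=1)
        abund_ok = min_in > max_out
        margin = min_in - max_out
    else:
        n_outside_on = np.zeros(len(cell_probs), dtype=int)
        out_ok = np.ones(len(cell_probs), dtype=bool)
        margin = np.full(len(cell_probs), np.nan)
        abund_ok = out_ok
    keep = in_ok & out_ok & abund_ok
    return pd.DataFrame(
        {
            "min_in_P": np.nanmin(p_in, axis=1)[keep],
            "n_outside_on": np.asarray(n_outside_on)[keep].astype(int),
            "abundance_margin": np.asarray(margin)[keep],
        },
        index=cell_probs.index[keep],
    )


def find_exclusive_markers(
    probs: pd.DataFrame,
    target_units: set[str] | list[str],
    background_units: set[str] | list[str],
    on_cut: float = 0.8,
    off_cut: float = 0.2,
) -> list[str]:
    """Genes on (P >= ``on_cut``) in every target unit and off (P <= ``off_cut``)
    in every background unit — e.g. expressed in dissected tissues but in none
    of the profiled cell types, marking unprofiled cells."""
    target = sorted(set(target_units))
    background = sorted(set(background_units))
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    overlap = set(target) & set(background)
    if overlap:
        raise ValueError(f"target and background overlap: {sorted(overlap)}")
    p_t = probs[target].to_numpy()
    p_b = probs[background].to_numpy()
    keep = (p_t >= on_cut).all(axis=1) & (p_b <= off_cut).all(axis=1)
    return list(probs.index[keep])


def expression_breadth(
    cell_states: pd.DataFrame,
    gene_groups: pd.DataFrame | None = None,
    min_group_size: int = 10,
) -> tuple[pd.Series, dict[str, pd.Series] | None]:
    """Number of cells calling each gene on; optionally grouped distributions.

    ``gene_groups`` has columns gene, group. Only groups with at least
    ``min_group_size`` member genes present in the state matrix are
    summarized.
    """
    breadth = (cell_states == STATE_ON).sum(axis=1)
    breadth.name = "breadth"
    if gene_groups is None:
        return breadth, None
    groups: dict[str, pd.Series] = {}
    for name, sub in gene_groups.groupby("group"):
        members = [g for g in sub["gene"] if g in breadth.index]
        if len(members) >= min_group_size:
            groups[str(name)] = breadth.loc[members]
    return breadth, groups
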