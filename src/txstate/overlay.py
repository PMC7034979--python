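"""Receptor expression overlaid on connectome synapse tables.

Joins discretized expression with electron-microscopy connectivity: each
postsynaptic process at each presynaptic active zone is classified by whether
its cell type expresses at least one of a set of receptor genes. Here
discretization is binary — on when P(on) >= 0.8, off below — and cell types
absent from the expression matrix are labeled unknown. Also counts candidate
interacting protein pairs between two cell types from an undirected
protein-protein interaction table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYNAPSE_COLUMNS = ("pre_instance", "pre_type", "zone_id", "post_instance", "post_type")

EXPRESSING = "expressing"
NON_EXPRESSING = "non_expressing"
UNKNOWN = "unknown"


@dataclass
class OverlayResult:
    """Per-active-zone composition of receptor-expressing partners."""

    instance: str  # representative presynaptic instance used
    zone_composition: pd.DataFrame  # zone_id x {expressing, non_expressing, unknown}
    partner_classes: pd.Series  # post_type -> class
    partner_synapses: pd.Series  # post_type -> synapse count (>= min_synapses)
    receptor_states: pd.DataFrame  # post_type x receptor gene (bool)
    excluded_partners: pd.Series  # post_type -> synapse count below threshold


def _receptor_on(cell_states: pd.DataFrame, receptor_genes: list[str]) -> pd.DataFrame:
    """Binary on/off per (receptor gene, cell type): on iff the state is 'on'.

    Works on a discretized state matrix (on/off/ambiguous) or a probability
    matrix; an ambiguous three-state call has P < 0.8 and therefore maps to
    off under the binary rule used for synapse overlays.
    """
    missing = [g for g in receptor_genes if g not in cell_states.index]
    if missing:
        raise ValueError(f"receptor genes absent from matrix: {missing}")
    block = cell_states.loc[receptor_genes]
    if block.to_numpy().dtype.kind in "fc":
        return block.astype(float) >= 0.8
    return block == "on"


def overlay_receptor_states(
    synapses: pd.DataFrame,
    cell_states: pd.DataFrame,
    receptor_genes: list[str],
    min_synapses: int = 5,
    presyn_type: str | None = None,
) -> OverlayResult:
    """Classify postsynaptic partners of one presynaptic cell by receptor state.

    Selects the presynaptic instance of ``presyn_type`` with the most
    distinct synaptic partners, drops partner types below ``min_synapses``
    total synapses, and labels every remaining postsynaptic process at every
    active zone as expressing (>= 1 receptor gene on), non-expressing (all
    off) or unknown (cell type not profiled).
    """
    missing_cols = [c for c in SYNAPSE_COLUMNS if c not in synapses.columns]
    if missing_cols:
        raise ValueError(f"synapse table is missing columns: {missing_cols}")
    if presyn_type is None:
        raise ValueError("presyn_type is required")
    pre = synapses.loc[synapses["pre_type"] == presyn_type]
    if pre.empty:
        raise ValueError(f"presynaptic type {presyn_type!r} absent from synapse table")
    on = _receptor_on(cell_states, list(receptor_genes))

    # representative instance: the one with the most distinct partners
    partner_counts = pre.groupby("pre_instance")["post_instance"].nunique()
    instance = partner_counts.sort_index().idxmax()
    rows = pre.loc[pre["pre_instance"] == instance]

    per_type = rows.groupby("post_type").size().sort_index()
    kept_types = per_type[per_type >= min_synapses]
    excluded = per_type[per_type < min_synapses]
    if len(excluded):
        logger.info(
            "partner types below %d synapses excluded: %s",
            min_synapses,
            list(excluded.index),
        )
    rows = rows.loc[rows["post_type"].isin(kept_types.index)]

    def classify(post_type: str) -> str:
        if post_type not in on.columns:
            return UNKNOWN
        return EXPRESSING if bool(on[post_type].any()) else NON_EXPRESSING

    classes = pd.Series(
        {t: classify(t) for t in kept_types.index}, name="class"
    ).sort_index()
    zone = (
        rows.assign(cls=rows["post_type"].map(classes))
        .groupby(["zone_id", "cls"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[EXPRESSING, NON_EXPRESSING, UNKNOWN], fill_value=0)
    )
    zone.columns.name = None
    profiled = [t for t in kept_types.index if t in on.columns]
    receptor_states = on[profiled].T if profiled else pd.DataFrame(columns=receptor_genes)
    return OverlayResult(
        instance=str(instance),
        zone_composition=zone,
        partner_classes=classes,
        partner_synapses=kept_types,
        receptor_states=receptor_states,
        excluded_partners=excluded,
    )


def count_interacting_pairs(
    cell_states: pd.DataFrame,
    interactions: pd.DataFrame,
    cell_x: str,
    cell_y: str,
) -> int:
    """Candidate trans interactions between two cells' expressed proteins.

    Counts unordered interaction pairs (a, b) where a is on in ``cell_x`` and
    b on in ``cell_y``, or vice versa; each table pair counts at most once.
    Homotypic queries (x == y) are allowed and count self-consistent pairs
    once.
    """
    for cell in (cell_x, cell_y):
        if cell not in cell_states.columns:
            raise ValueError(f"cell {cell!r} absent from the state matrix")
    if interactions.empty:
        return 0
    on = cell_states == "on"
    on_x = set(cell_states.index[on[cell_x]])
    on_y = set(cell_states.index[on[cell_y]])
    seen: set[frozenset] = set()
    count = 0
    for a, b in interactions[["gene_a", "gene_b"]].itertuples(index=False):
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        if (a in on_x and b in on_y) or (b in on_x and a in on_y):
            count += 1
    return count
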