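"""Synthetic bulk-transcriptome catalogs with known on/off ground truth.

The generator emulates the statistical structure the mixture model assumes:
per-gene two-component log-normal abundances with a shared within-state
spread, genes that are bimodal across cell types alongside genes that are
uniformly expressed (housekeeping-like) or uniformly silent, transcript
carryover from a designated contaminant cell type whose most abundant
transcripts leak into every other sample, and dissected mixed-tissue samples
built as convex mixtures of cell-type profiles. Every draw is controlled by a
single seed, and a full truth table (per-gene parameters and per
gene x cell-type states) is returned for end-to-end evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, SampleMetadata

GENE_CLASSES = ("bimodal", "unimodal_on", "unimodal_off")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic catalog.

    ``gene_params`` has one row per gene (class, mu_off, mu_on, sigma, pi);
    ``states`` is a boolean genes x cell-types table of true on states;
    ``contamination`` records the carryover fraction, the contaminant cell
    type and the designated high-abundance genes; ``dissected_weights`` holds
    the mixture weights of each dissected pseudo-sample; ``params`` echoes
    every generator argument including the seed.
    """

    gene_params: pd.DataFrame
    states: pd.DataFrame
    contamination: dict
    dissected_weights: pd.DataFrame
    params: dict


@dataclass
class SyntheticCatalog:
    matrix: AbundanceMatrix
    metadata: SampleMetadata
    truth: SyntheticTruth


@dataclass
class SyntheticFixtures:
    """Companion fixtures derived from a catalog's ground truth."""

    benchmark: pd.DataFrame
    synapses: pd.DataFrame
    interactions: pd.DataFrame
    sc_counts: pd.DataFrame
    sc_labels: pd.Series
    cluster_sizes: pd.Series
    true_counts: pd.Series
    merged_cluster: tuple[str, ...]


def generate_catalog(
    n_genes: int = 2000,
    n_celltypes: int = 30,
    drivers_per_type: tuple[int, int] = (1, 2),
    replicates: tuple[int, int] = (2, 3),
    frac_bimodal: float = 0.6,
    separation_sd_range: tuple[float, float] = (3.0, 6.0),
    sigma_range: tuple[float, float] = (0.3, 0.8),
    carryover: float = 0.05,
    n_carryover_genes: int = 10,
    carryover_min_tpm: float = 1000.0,
    min_gap: float = 2.0,
    n_dissected: int = 2,
    noise: str = "lognormal",
    t_dof: float = 4.0,
    seed: int | None = 0,
) -> SyntheticCatalog:
    """Simulate a cell-type catalog of relative transcript abundances.

    Bimodal genes switch between a low off level (mu_off ~ U(0, 2) natural-log
    TPM, i.e. ~1-7 TPM) and an on level ``mu_on = mu_off + max(separation *
    sigma, min_gap)``, so on states span roughly 7-900 TPM and are always at
    least ``min_gap`` natural-log units (~7-fold) above the off state.
    Unimodal-on genes (U(4.5, 7.5)) are expressed everywhere; unimodal-off
    genes (U(-1, 1)) are silent everywhere. A designated photoreceptor-like
    cell type contributes carryover: its transcripts above
    ``carryover_min_tpm`` leak into every other sample at fraction
    ``carryover`` (with lognormal jitter, sd 0.3). ``noise='student_t'``
    switches to heavier-tailed within-state noise for misspecification tests.
    Columns are renormalized to one million transcripts.
    """
    if not 0 <= frac_bimodal <= 1:
        raise ValueError("frac_bimodal must be in [0, 1]")
    if not 0 <= carryover < 1:
        raise ValueError("carryover must be in [0, 1)")
    if noise not in ("lognormal", "student_t"):
        raise ValueError(f"unknown noise model {noise!r}")
    if n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)

    width = max(4, len(str(n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    cells = [f"cell_{i:02d}" for i in range(n_celltypes)]
    contaminant_cell = cells[0]

    # --- per-gene parameters -------------------------------------------------
    rest = (1.0 - frac_bimodal) / 2.0
    classes = rng.choice(GENE_CLASSES, size=n_genes, p=[frac_bimodal, rest, rest])
    sigma = rng.uniform(*sigma_range, size=n_genes)
    sep = rng.uniform(*separation_sd_range, size=n_genes)
    mu_on = np.full(n_genes, np.nan)
    mu_off = np.full(n_genes, np.nan)
    pi = np.full(n_genes, np.nan)

    bim = classes == "bimodal"
    mu_off[bim] = rng.uniform(0.0, 2.0, size=bim.sum())
    gap = np.maximum(sep[bim] * sigma[bim], min_gap)
    mu_on[bim] = mu_off[bim] + gap
    pi[bim] = rng.uniform(0.15, 0.85, size=bim.sum())
    uon = classes == "unimodal_on"
    mu_on[uon] = rng.uniform(4.5, 7.5, size=uon.sum())
    uoff = classes == "unimodal_off"
    mu_off[uoff] = rng.uniform(-1.0, 1.0, size=uoff.sum())

    # true states per (gene, cell)
    states = np.zeros((n_genes, n_celltypes), dtype=bool)
    states[bim] = rng.random((int(bim.sum()), n_celltypes)) < pi[bim, None]
    states[uon] = True

    # carryover genes: expressed only in the contaminant cell type, at very
    # high abundance (rhodopsin-like)
    n_co = min(n_carryover_genes, int(bim.sum()))
    co_idx = rng.choice(np.flatnonzero(bim), size=n_co, replace=False)
    states[co_idx] = False
    states[co_idx, 0] = True
    mu_on[co_idx] = rng.uniform(7.5, 9.0, size=n_co)
    mu_off[co_idx] = rng.uniform(-1.0, 0.5, size=n_co)
    pi[co_idx] = 1.0 / n_celltypes

    # --- samples -------------------------------------------------------------
    sample_rows = []
    sample_cell_idx = []
    for ci, cell in enumerate(cells):
        n_drv = int(rng.integers(drivers_per_type[0], drivers_per_type[1] + 1))
        for d in range(1, n_drv + 1):
            driver = f"{cell}_d{d}"
            n_rep = int(rng.integers(replicates[0], replicates[1] + 1))
            for r in range(1, n_rep + 1):
                sample_rows.append((f"{driver}_r{r}", driver, cell, r, "cell_catalog"))
                sample_cell_idx.append(ci)
    n_cat = len(sample_rows)
    sample_cell_idx = np.asarray(sample_cell_idx)

    # latent per-(gene, cell) means
    mean_gc = np.where(states, mu_on[:, None], mu_off[:, None])  # (G, C)
    mean_gs = mean_gc[:, sample_cell_idx]  # (G, n_cat)
    if noise == "lognormal":
        eps = rng.standard_normal((n_genes, n_cat))
    else:
        eps = rng.standard_t(t_dof, size=(n_genes, n_cat)) / np.sqrt(t_dof / (t_dof - 2.0))
    values = np.exp(mean_gs + sigma[:, None] * eps)

    # carryover: the contaminant cell's most abundant transcripts leak into
    # every non-contaminant sample
    contam_profile = np.where(states[:, 0], np.exp(mu_on), np.exp(np.nan_to_num(mu_off, nan=-np.inf)))
    contam_profile = np.where(np.isnan(contam_profile), 0.0, contam_profile)
    contam_profile = np.where(contam_profile >= carryover_min_tpm, contam_profile, 0.0)
    other = sample_cell_idx != 0
    if carryover > 0 and other.any():
        # carryover varies over orders of magnitude between preparations
        jitter = np.exp(1.0 * rng.standard_normal((n_genes, int(other.sum()))))
        values[:, other] = (1 - carryover) * values[:, other] + carryover * (
            contam_profile[:, None] * jitter
        )

    # dissected pseudo-samples: convex mixtures of expected cell-type profiles
    expected_gc = np.exp(mean_gc)
    weights = rng.dirichlet(np.ones(n_celltypes), size=n_dissected)  # (n_dis, C)
    dis_values = expected_gc @ weights.T  # (G, n_dis)
    dis_values = dis_values * np.exp(0.2 * rng.standard_normal(dis_values.shape))
    dis_ids = [f"dissected_{k + 1}" for k in range(n_dissected)]
    for k, sid in enumerate(dis_ids):
        sample_rows.append((sid, sid, sid, 1, "dissected"))

    all_values = np.concatenate([values, dis_values], axis=1)
    all_values *= 1e6 / all_values.sum(axis=0, keepdims=True)

    sample_ids = [r[0] for r in sample_rows]
    matrix = AbundanceMatrix(pd.DataFrame(all_values, index=genes, columns=sample_ids))
    metadata = SampleMetadata(
        pd.DataFrame(sample_rows, columns=["sample_id", "driver_id", "cell_type_id", "replicate", "sample_class"])
    )
    gene_params = pd.DataFrame(
        {
            "class": classes,
            "mu_off": mu_off,
            "mu_on": mu_on,
            "sigma": sigma,
            "pi": pi,
        },
        index=pd.Index(genes, name="gene"),
    )
    truth = SyntheticTruth(
        gene_params=gene_params,
        states=pd.DataFrame(states, index=genes, columns=cells),
        contamination={
            "fraction": carryover,
            "contaminant_cell": contaminant_cell,
            "carryover_genes": [genes[i] for i in sorted(co_idx)],
            "min_tpm": carryover_min_tpm,
        },
        dissected_weights=pd.DataFrame(weights, index=dis_ids, columns=cells),
        params={
            "n_genes": n_genes,
            "n_celltypes": n_celltypes,
            "drivers_per_type": drivers_per_type,
            "replicates": replicates,
            "frac_bimodal": frac_bimodal,
            "separation_sd_range": separation_sd_range,
            "sigma_range": sigma_range,
            "carryover": carryover,
            "n_carryover_genes": n_carryover_genes,
            "carryover_min_tpm": carryover_min_tpm,
            "n_dissected": n_dissected,
            "noise": noise,
            "seed": seed,
        },
    )
    return SyntheticCatalog(matrix=matrix, metadata=metadata, truth=truth)


def generate_fixtures(
    truth: SyntheticTruth,
    seed: int | None = 0,
    n_benchmark: int = 200,
    benchmark_error_rate: float = 0.0,
    cells_per_cluster: tuple[int, int] = (30, 250),
    sc_depth: tuple[int, int] = (20_000, 60_000),
    n_interactions: int = 40,
    n_zones: int = 30,
) -> SyntheticFixtures:
    """Derive benchmark, connectome and single-cell fixtures from a truth table.

    The single-cell fixture draws multinomial counts around each cell type's
    expected profile; the last two cell types are deliberately merged into one
    cluster to exercise one-cluster/many-types matching. ``true_counts`` are
    proportional to the simulated cluster sizes by construction, so
    observed/expected ratios against them equal one.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.states.index)
    cells = list(truth.states.columns)
    n_genes, n_cells = truth.states.shape

    # --- protein benchmark ----------------------------------------------------
    gi = rng.integers(0, n_genes, size=n_benchmark)
    ci = rng.integers(0, n_cells, size=n_benchmark)
    seen = set()
    rows = []
    truth_mat = truth.states.to_numpy()
    for g, c in zip(gi, ci):
        if (g, c) in seen:
            continue
        seen.add((g, c))
        state = bool(truth_mat[g, c])
        if benchmark_error_rate and rng.random() < benchmark_error_rate:
            state = not state
        rows.append((genes[g], cells[c], "on" if state else "off"))
    benchmark = pd.DataFrame(rows, columns=["gene", "cell_type", "expected_state"])

    # --- synapse table ---------------------------------------------------------
    presyn_type = cells[0]
    syn_rows = []
    partner_pool = cells[1:] + ["unprofiled_t1", "unprofiled_t2"]
    for inst, zone_count in (("inst_a", n_zones), ("inst_b", max(2, n_zones // 4))):
        for z in range(zone_count):
            zone = f"{inst}_az{z:03d}"
            n_partners = int(rng.integers(1, 5))
            for p in range(n_partners):
                post = partner_pool[int(rng.integers(0, len(partner_pool)))]
                syn_rows.append((inst, presyn_type, zone, f"{post}_i{p}", post))
    synapses = pd.DataFrame(
        syn_rows,
        columns=["pre_instance", "pre_type", "zone_id", "post_instance", "post_type"],
    )

    # --- protein interaction table ---------------------------------------------
    pairs = set()
    while len(pairs) < min(n_interactions, n_genes * (n_genes - 1) // 2):
        a, b = rng.integers(0, n_genes, size=2)
        if a == b:
            continue
        pairs.add((genes[min(a, b)], genes[max(a, b)]))
    interactions = pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"])

    # --- synthetic single-cell counts -------------------------------------------
    params = truth.gene_params
    mean_gc = np.where(
        truth_mat,
        params["mu_on"].to_numpy()[:, None],
        params["mu_off"].to_numpy()[:, None],
    )
    expected = np.exp(mean_gc)
    probs = expected / expected.sum(axis=0, keepdims=True)

    merged = (cells[-2], cells[-1])
    merged_label = f"merged_{cells[-2]}_{cells[-1]}"
    labels_of_cell = {c: (merged_label if c in merged else f"cluster_{c}") for c in cells}

    sizes = rng.integers(cells_per_cluster[0], cells_per_cluster[1] + 1, size=n_cells)
    counts_cols: list[np.ndarray] = []
    labels: list[str] = []
    col_ids: list[str] = []
    for c_idx, cell in enumerate(cells):
        p = probs[:, c_idx]
        for j in range(sizes[c_idx]):
            depth = int(rng.integers(sc_depth[0], sc_depth[1] + 1))
            counts_cols.append(rng.multinomial(depth, p))
            labels.append(labels_of_cell[cell])
            col_ids.append(f"{cell}_sc{j:04d}")
    sc_counts = pd.DataFrame(
        np.column_stack(counts_cols), index=genes, columns=col_ids
    )
    sc_labels = pd.Series(labels, index=col_ids, name="cluster")

    cluster_sizes = sc_labels.value_counts().sort_index()
    # anatomical counts proportional to cluster sizes by construction
    per_cell_sizes = pd.Series(sizes, index=cells)
    true_counts = pd.Series(0, index=sorted(cluster_sizes.index), dtype=int)
    for cell in cells:
        true_counts[labels_of_cell[cell]] += int(per_cell_sizes[cell]) * 5
    return SyntheticFixtures(
        benchmark=benchmark,
        synapses=synapses,
        interactions=interactions,
        sc_counts=sc_counts,
        sc_labels=sc_labels,
        cluster_sizes=cluster_sizes,
        true_counts=true_counts,
        merged_cluster=merged,
    )
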