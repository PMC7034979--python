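"""End-to-end orchestration: simulate -> infer -> discretize -> downstream.

A single flat :class:`RunConfig` drives every stage; each stage reads its
inputs from, and writes its outputs to, the run directory, so stages can be
re-run individually and a failed stage leaves earlier outputs intact. A
manifest (config hash, package version, seeds, priors) makes runs
reproducible: the same config yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, simulate, states, tree
from .mixture import MixtureConfig, infer_expression_probabilities
from . import deconvolution as deconv
from . import overlay as overlay_mod

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGE_ORDER = (
    "simulate",
    "filter",
    "infer",
    "discretize",
    "markers",
    "benchmark",
    "tree",
    "deconvolve",
    "overlay",
)


@dataclass
class RunConfig:
    """Flat configuration; defaults follow the printed analysis constants."""

    out_dir: str = "txstate_run"
    stages: tuple[str, ...] = ("simulate", "infer", "discretize")
    seed: int = 0

    # inputs (filled by the simulate stage when it runs)
    abundance: str | None = None
    metadata: str | None = None
    coding_list: str | None = None
    exclude_list: str | None = None
    benchmark: str | None = None
    sc_matrix: str | None = None
    sc_labels: str | None = None
    synapses: str | None = None
    interactions: str | None = None
    receptors: tuple[str, ...] = ()
    presyn_type: str | None = None
    marker_group: tuple[str, ...] = ()

    # gene pre-filter
    min_tpm: float = 10.0
    renormalize: bool = False

    # sampler / model selection
    chains: int = 4
    iters: int = 500
    folds: int = 10
    floor: float = 0.01

    # discretization and markers
    on_cut: float = 0.8
    off_cut: float = 0.2
    marker_in_cut: float = 0.9
    marker_max_outside: int = 2

    # expression tree
    tree_min_on_mean: float = 3.0
    tree_min_separation: float = 1.5
    n_boot: int = 1000

    # deconvolution / overlay
    top_k: int = 50
    min_synapses: int = 5

    # synthetic data
    n_genes: int = 2000
    n_celltypes: int = 30
    frac_bimodal: float = 0.6
    carryover: float = 0.05

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _out(config: RunConfig, name: str) -> Path:
    return Path(config.out_dir) / name


def _require(config: RunConfig, stage: str, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = _out(config, name)
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {p}; run the producing stage first"
            )
        paths.append(p)
    return paths


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in dependency order; returns the run dir."""
    unknown = [s for s in config.stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "priors": {
            "mu": "Normal(7, 5), ordered",
            "sigma": "HalfNormal(3)",
            "pi": "Uniform(0, 1)",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    for stage in STAGE_ORDER:
        if stage in config.stages:
            logger.info("running stage %s", stage)
            _STAGES[stage](config)
    return out


def _stage_simulate(config: RunConfig) -> None:
    cat = simulate.generate_catalog(
        n_genes=config.n_genes,
        n_celltypes=config.n_celltypes,
        frac_bimodal=config.frac_bimodal,
        carryover=config.carryover,
        seed=config.seed,
    )
    io.write_abundance(cat.matrix, _out(config, "abundance.tsv"))
    io.write_metadata(cat.metadata, _out(config, "metadata.tsv"))
    io.write_matrix(cat.truth.states.astype(int), _out(config, "truth_states.tsv"))
    cat.truth.gene_params.to_csv(_out(config, "truth_gene_params.tsv"), sep="\t")
    fix = simulate.generate_fixtures(cat.truth, seed=config.seed)
    fix.benchmark.to_csv(_out(config, "benchmark.tsv"), sep="\t", index=False)
    fix.synapses.to_csv(_out(config, "synapses.tsv"), sep="\t", index=False)
    fix.interactions.to_csv(_out(config, "interactions.tsv"), sep="\t", index=False)
    io.write_matrix(fix.sc_counts, _out(config, "sc_counts.tsv"))
    fix.sc_labels.rename_axis("cell").to_frame().to_csv(_out(config, "sc_labels.tsv"), sep="\t")


def _stage_filter(config: RunConfig) -> None:
    abundance = config.abundance or _out(config, "abundance.tsv")
    metadata = config.metadata or _out(config, "metadata.tsv")
    matrix, meta = io.read_inputs(abundance, metadata)
    coding = (
        set(Path(config.coding_list).read_text().split())
        if config.coding_list
        else set(matrix.genes)
    )
    exclude = (
        set(Path(config.exclude_list).read_text().split()) if config.exclude_list else set()
    )
    filtered, report = io.filter_genes(
        matrix, coding, min_tpm=config.min_tpm, exclude=exclude, renormalize=config.renormalize
    )
    logger.info("%s", report)
    io.write_abundance(filtered, _out(config, "abundance_filtered.tsv"))
    io.write_metadata(meta, _out(config, "metadata.tsv"))


def _stage_infer(config: RunConfig) -> None:
    abundance = (
        _out(config, "abundance_filtered.tsv")
        if _out(config, "abundance_filtered.tsv").exists()
        else (config.abundance or _out(config, "abundance.tsv"))
    )
    metadata = config.metadata or _out(config, "metadata.tsv")
    if not Path(abundance).exists():
        raise FileNotFoundError(
            "stage 'infer' needs an abundance matrix; run simulate/filter or set config.abundance"
        )
    matrix, meta = io.read_inputs(abundance, metadata)
    mix = MixtureConfig(
        chains=config.chains,
        iters=config.iters,
        folds=config.folds,
        floor=config.floor,
        seed=config.seed,
    )
    result = infer_expression_probabilities(matrix, meta, mix)
    io.write_matrix(result.sample_probs, _out(config, "probabilities_sample.tsv"))
    io.write_matrix(result.driver_probs, _out(config, "probabilities_driver.tsv"))
    io.write_matrix(result.cell_probs, _out(config, "probabilities_cell.tsv"))
    if result.dissected_probs is not None:
        io.write_matrix(result.dissected_probs, _out(config, "probabilities_dissected.tsv"))
    io.write_matrix(result.fits, _out(config, "gene_fits.tsv"))
    # cell-level mean abundance, used by the marker stage
    cell_of = meta.cell_of()
    catalog = meta.catalog_samples()
    mean_ab = matrix.data[catalog].T.groupby(cell_of.loc[catalog]).mean().T
    io.write_matrix(mean_ab, _out(config, "abundance_cell_mean.tsv"))


def _stage_discretize(config: RunConfig) -> None:
    for level in ("sample", "driver", "cell"):
        (path,) = _require(config, "discretize", f"probabilities_{level}.tsv")
        probs = io.read_matrix(path)
        st = states.discretize(probs, config.on_cut, config.off_cut)
        io.write_matrix(st, _out(config, f"states_{level}.tsv"))


def _stage_markers(config: RunConfig) -> None:
    probs_p, ab_p = _require(
        config, "markers", "probabilities_cell.tsv", "abundance_cell_mean.tsv"
    )
    probs = io.read_matrix(probs_p)
    abundance = io.read_matrix(ab_p)
    group = list(config.marker_group) or list(probs.columns)
    markers = states.find_group_markers(
        probs, abundance, group, config.marker_in_cut, config.marker_max_outside
    )
    markers.insert(0, "group", "+".join(group) if len(group) < 6 else f"{len(group)}_cells")
    io.write_matrix(markers, _out(config, "markers.tsv"))


def _stage_benchmark(config: RunConfig) -> None:
    bench_path = config.benchmark or _out(config, "benchmark.tsv")
    (states_p,) = _require(config, "benchmark", "states_cell.tsv")
    (probs_p,) = _require(config, "benchmark", "probabilities_cell.tsv")
    bench = pd.read_csv(bench_path, sep="\t")
    st = io.read_matrix(states_p, numeric=False)
    probs = io.read_matrix(probs_p)
    result = states.benchmark_concordance(st, probs, bench)
    summary = pd.DataFrame(
        {
            "value": [
                result.concordance,
                len(result.matches),
                len(result.mismatches),
                len(result.ambiguous),
                len(result.unresolved),
            ]
        },
        index=["concordance", "matches", "mismatches", "ambiguous", "unresolved"],
    )
    io.write_matrix(summary, _out(config, "benchmark_summary.tsv"), index_label="metric")


def _stage_tree(config: RunConfig) -> None:
    probs_p, fits_p = _require(config, "tree", "probabilities_cell.tsv", "gene_fits.tsv")
    probs = io.read_matrix(probs_p)
    fits = io.read_matrix(fits_p, numeric=False)
    for col in ("mu_on", "mu_off"):
        fits[col] = pd.to_numeric(fits[col], errors="coerce")
    genes = tree.select_informative_genes(
        fits, config.tree_min_on_mean, config.tree_min_separation
    )
    if len(genes) < 3:
        raise ValueError("fewer than 3 informative genes; cannot build a tree")
    seqs = tree.encode_state_sequences(probs, genes, config.on_cut, config.off_cut)
    result = tree.bootstrap_support(seqs, n_boot=config.n_boot, seed=config.seed)
    _out(config, "tree.nwk").write_text(result.newick() + "\n")
    pd.DataFrame(
        {"support": list(result.supports.values())},
        index=[",".join(sorted(b)) for b in result.bipartitions().values()],
    ).to_csv(_out(config, "tree_supports.tsv"), sep="\t", index_label="bipartition")


def _stage_deconvolve(config: RunConfig) -> None:
    sc_matrix = config.sc_matrix or _out(config, "sc_counts.tsv")
    sc_labels = config.sc_labels or _out(config, "sc_labels.tsv")
    for p in (sc_matrix, sc_labels):
        if not Path(p).exists():
            raise FileNotFoundError(f"stage 'deconvolve' needs {p}")
    (ab_p,) = _require(config, "deconvolve", "abundance_cell_mean.tsv")
    counts = io.read_matrix(sc_matrix)
    labels = pd.read_csv(sc_labels, sep="\t", index_col=0)["cluster"]
    bulk = io.read_matrix(ab_p)
    clusters = deconv.cluster_profiles(counts, labels)
    result = deconv.deconvolve(bulk, clusters, k=config.top_k)
    io.write_matrix(result.coefficients, _out(config, "deconv_coefficients.tsv"), index_label="bulk_profile")
    io.write_matrix(result.normalized, _out(config, "deconv_normalized.tsv"), index_label="bulk_profile")
    _out(config, "deconv_genes.txt").write_text("\n".join(result.genes) + "\n")


def _stage_overlay(config: RunConfig) -> None:
    syn_path = config.synapses or _out(config, "synapses.tsv")
    if not Path(syn_path).exists():
        raise FileNotFoundError(f"stage 'overlay' needs {syn_path}")
    (states_p,) = _require(config, "overlay", "states_cell.tsv")
    synapses = pd.read_csv(syn_path, sep="\t")
    st = io.read_matrix(states_p, numeric=False)
    receptors = list(config.receptors) or list(st.index[:1])
    presyn = config.presyn_type or synapses["pre_type"].iloc[0]
    result = overlay_mod.overlay_receptor_states(
        synapses, st, receptors, config.min_synapses, presyn
    )
    io.write_matrix(result.zone_composition, _out(config, "overlay_zones.tsv"), index_label="zone_id")
    result.partner_classes.rename_axis("post_type").to_frame().to_csv(
        _out(config, "overlay_partners.tsv"), sep="\t"
    )


_STAGES = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "infer": _stage_infer,
    "discretize": _stage_discretize,
    "markers": _stage_markers,
    "benchmark": _stage_benchmark,
    "tree": _stage_tree,
    "deconvolve": _stage_deconvolve,
    "overlay": _stage_overlay,
}
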