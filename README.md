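# txstate

Infer binary on/off expression states — with calibrated probabilities — from
bulk RNA-seq catalogs of genetically defined cell types, and run the
analyses that build on those calls: marker detection, expression-state trees
of cell types, deconvolution of bulk profiles against single-cell clusters,
and receptor-expression overlays on connectome synapse tables.

## Who this is for

Projects that profile many cell populations in bulk (e.g. nuclei
affinity-purified via driver lines, one transcriptome per driver and
replicate) face the same question per gene and cell type: *is this gene
expressed here, or is the signal carryover, noise, or ambiguity?* Thresholding
TPM does not answer it — abundance scales differ across genes by orders of
magnitude, and highly abundant transcripts from one cell type contaminate
the others. `txstate` answers it with a per-gene mixture model and reports a
probability, not a cutoff.

## The model

For each gene g, log abundance across samples is modeled as a two-component
normal mixture with a shared spread (the *off* and *on* states):

    log E_gs | z ~ N(mu_gz, sigma_g),   z in {off, on},  mu_g,off <= mu_g,on

    P(z_gc = on) = pi_g * prod_s p(E_gs | on)
                   ------------------------------------------------------
                   pi_g * prod_s p(E_gs | on) + (1 - pi_g) * prod_s p(E_gs | off)

with the product over a unit's replicate samples. The shared sigma makes
P(on) monotone in abundance. A competing single log-normal ("unimodal")
model catches genes that never switch within the catalog; the winner is
decided by 10-fold cross-validated expected log predictive density (elpd),
keeping the bimodal model only when its advantage exceeds twice its standard
error. Unimodal genes are classified on/off against global on/off
distributions pooled from confidently bimodal genes. Priors: component
means N(7, 5) on log-TPM (ordered), sigma ~ Half-Normal(3), pi ~ Uniform;
posterior sampling is a vectorized Gibbs sampler, 4 chains x 500 iterations
by default. See `docs/methods.md` for the full treatment.

## Worked example

Simulate a small catalog with known ground truth (300 genes, 10 cell
types), infer states, discretize, and build the cell-type tree:

```sh
txstate simulate --out-dir demo --seed 7 --n-genes 300 --n-celltypes 10
txstate infer      --out-dir demo --seed 7 --chains 2 --iters 300
txstate discretize --out-dir demo
txstate tree       --out-dir demo --n-boot 100
```

`demo/gene_fits.tsv` records, per gene, the selected model and its
parameters. The strongest bimodal gene in this run, `g0127`, fits

    mu_off = 4.43, mu_on = 7.61, sigma = 0.44, pi = 0.45
    delta_elpd = 23.5, se = 2.84   (bimodal wins: 23.5 > 2 x 2.84)

i.e. an off state near e^4.4 ~ 84 TPM, an on state near e^7.6 ~ 2000 TPM,
and on-probabilities per cell type (`demo/probabilities_cell.tsv`):

    cell_00  cell_01  cell_02  cell_03  cell_04  cell_05 ...
    0.000    1.000    0.000    1.000    1.000    0.000

which discretize (on if P >= 0.8, off if P <= 0.2) to exactly the simulated
truth for this gene: on in cell_01, cell_03, cell_04, cell_08, off
elsewhere. Across all 300 x 10 gene/cell pairs this compact run recovers
83% of true states (small catalogs carry strong composition noise; the
2000-gene configuration recovers ~97%). `demo/tree.nwk` holds the
balanced-minimum-evolution tree of the 10 cell types with bootstrap
supports as internal node labels:

    (cell_00:0.187,cell_05:0.179,(cell_09:0.156,(((cell_02:0.145,cell_07:0.160)0.44:...

Every stage is also a library call (`txstate.infer_expression_probabilities`,
`txstate.discretize`, `txstate.balanced_me_tree`, `txstate.deconvolve`,
`txstate.overlay_receptor_states`, ...) operating on pandas objects; the CLI
is a thin wrapper.

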