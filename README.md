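# scfate

Analysis toolkit for single-cell qPCR studies of hematopoietic stem-cell
(HSC) fate priming. It addresses the question of *when* transplanted HSCs
commit to restricted myeloid fates — before or after their first division,
and before or after S-phase entry — by combining four computational
readouts on sorted single cells:

1. **Division gating** from dilution of a covalent cell-tracing dye
   (CellTrace-style): intensity halves per division, so undivided cells are
   gated against the median log2 intensity of an undivided reference
   population (standard gate at −0.5 log2 units; a stringent gate with an
   ambiguous buffer zone).
2. **Hurdle-model differential expression** for the bimodal expression of
   single cells: a gene is compared between two cell groups jointly on its
   detection frequency (Bernoulli part) and its mean positive expression
   (Gaussian part), with a chi-square likelihood-ratio test on the summed
   statistic (df = 2, or 1 when one group is entirely undetected).
3. **Cell-cycle phase assignment** from phase-specific gene signatures:
   per-gene max normalization, average expression of 4 G1 genes (*Ccne1,
   Cdk2, Cdkn1a, Cdkn1c*) and 11 S/G2/M genes (*Cdkn2d, E2f4, Cdk6, Cdkn2c,
   Ccng2, Ccnf, Mki67, Ccna2, Ccnb1, Ccnb2, Cdc20*), and a G0/G1 vs S/G2/M
   call whose S/G2/M-score cutoff is calibrated so that ~90% of a
   control-HSC reference — the known quiescent fraction of C57Bl/6 HSCs —
   falls in G0/G1.
4. **Population structure**: t-SNE embeddings, consensus k-means (k = 2
   over many restarts) and hierarchical clustering, with adjusted-Rand
   agreement between labelings — used to show that undivided restricted
   progenitors (PreME/PreMeg) form MEP/platelet-gene expression clusters
   distinct from HSCs, independent of cell-cycle phase.

Because raw data of this kind are rarely deposited, the package ships a
**synthetic-data generator** that reproduces the statistical structure the
analyses assume — bimodal detection with population-specific detection
probability π and positive-expression mean μ, phase-structured cell-cycle
genes, batch offsets, and log2-halving dye dilution — so the whole pipeline
is testable end to end with known ground truth. See `docs/methods.md` for
the model details and parameter defaults.

## Worked example

Run the full synthetic pipeline (simulate → gate divisions → hurdle DE →
phase calls → clustering):

```sh
scfate pipeline --seed 7 --outdir demo
```

prints

```
{
 "cluster_agreement": {
  "accuracy_under_best_matching": 1.0,
  "ari": 1.0
 },
 "reference_g0g1_fraction": 0.9
}
```

i.e. k = 2 consensus k-means on the MEP/platelet genes recovers the
HSC vs PreMeg split perfectly (adjusted Rand index 1.0), and 90% of the
1000 simulated control HSCs are classified G0/G1 after calibration —
the configured reference level. `demo/summary.json` holds the full
machine-readable report; for this seed it includes the phase census of the
84-cell cohort (`{"G0G1": 58, "SG2M": 26}`), the division gate census
(62 undivided, 22 divided of the simulated 30% divided fraction), and the
MEP/platelet fold-change table, e.g. PreMeg cells at 13.3× (G0/G1) and
12.9× (S/G2/M) the mean expression of G0/G1 HSCs — lineage-gene expression
high in *both* phases, the signature of differentiation that does not wait
for S/G2/M. The per-gene hurdle table (`demo/hurdle_de.tsv`) ranks the
MEP/platelet genes on top; its strongest hit for this seed:

```
gene   freq_a  freq_b  pos_mean_a  pos_mean_b  lrt_total  p_value
Tal1   0.333   1.00    2.62        10.04       132.43     1.8e-29
```

(HSCs detect *Tal1* in 33% of cells at mean Et 2.6; PreMegs in 100% of
cells at 10.0; the two-part LRT is referred to chi-square with 2 df.)

Each stage is also available separately (`scfate simulate`, `preprocess`,
`de`, `cellcycle`, `cluster`, `division`) and as plain library functions
with identical results (`scfate.generate_cells`, `scfate.test_all_genes`,
`scfate.phase_scores`, …).

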