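# pitx1tools

Reusable, tested implementations of the computations behind a
single-enhancer-deletion study at a developmental limb-identity locus:
what happens to a gene's expression, to tissue composition, and to 3D
chromatin contacts when one enhancer (*Pen*) is removed from an otherwise
intact regulatory landscape.

The package is aimed at people analysing scRNA-seq and Capture-HiC data
around a single target gene, and at people who want to stress-test such
analyses on synthetic data with known ground truth.

## What it computes

**Three-class expression calling** (`pitx1tools.expression`).  Per-cell
target-gene expression is log-normalized as
`x = ln(1 + count / total × 10⁴)` and partitioned into non/low-
(`x ≤ 0.3`), intermediate- (`0.3 < x ≤ 1.45`) and high-expressing
(`x > 1.45`) cells.  The thresholds ship as frozen defaults; they can be
re-derived from data as the intersection points of two Gaussian-kernel
density estimates (`estimate_density` + `find_intersection`), which is how
such boundaries are defined in the first place.  QC filtering (≥ 200 genes,
mitochondrial fraction in [1%, 15%]), per-group class proportions and
non/low fold changes round out the stage.

**Differential proportion analysis** (`pitx1tools.composition`).  A
permutation test for shifts in cluster composition between two conditions.
Per cluster the statistic is the difference of within-condition
proportions.  The null re-partitions the pooled labels into the two
condition sizes (multivariate hypergeometric) and redraws an expected
fraction `p_mix` of each side i.i.d. from the pooled distribution;
`p_mix` interpolates between the exact permutation null (0) and the
multinomial bootstrap null (1).  P-values are add-one empirical,
`(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, two-sided, never exactly zero.
Defaults: `n_perm = 100,000`, `p_mix = 0.1`.

**Capture-HiC post-processing** (`pitx1tools.contacts`).  Mate pairs →
binned symmetric contact matrix → Knight–Ruiz balancing (Newton/CG
inner–outer iteration) → joint per-subdiagonal scaling of two maps (each
diagonal offset is rescaled to the average of the two maps' offset means,
cancelling distance decay) → signed subtraction map, with 99th-percentile
truncation for display.  Virtual-4C profiles count pairs with exactly one
mate in a viewpoint, bin the outside mate at 1 kb, average over 5 kb
intervals and export bedGraph.  The capture window and promoter viewpoint
of the original study ship as the preset `pitx1-mm9`
(chr13:54,000,001–57,300,000; viewpoint chr13:55,930,001–55,940,000).

**Bulk marker statistics** (`pitx1tools.bulk`).  RPKM, removal of genes
≤ 1 RPKM in every sample of a subset, per-gene z-scores, and
replicate-averaged log2 fold changes.

**Synthetic data** (`pitx1tools.simulate`).  Seeded generators for
cluster-structured cell tables (three-component expression mixture with
condition × cluster weights, back-converted to UMI counts) and for contact
pairs (power-law distance decay plus viewpoint–anchor loops via exact
rejection sampling), each returning a ground-truth record.

## Worked example

```python
import pitx1tools as pt

cells, truth = pt.gen_cells(pt.default_cell_config(seed=1))
kept, log = pt.qc_filter(cells)
classified = pt.classify_cells(pt.log_normalize(kept))
print(pt.class_proportions(classified, group_by="condition").round(3))
```

```
                     n_cells  frac_nonlow  frac_intermediate  frac_high
condition group
KO-HL     KO-HL         4471        0.980              0.020      0.000
PenDel-HL PenDel-HL     4610        0.360              0.369      0.270
WT-FL     WT-FL         4666        0.979              0.021      0.000
WT-HL     WT-HL         4642        0.207              0.400      0.393
```

The wildtype hindlimb splits ≈ 21 / 40 / 39 % across the three classes;
deleting the enhancer raises the non/low fraction to ≈ 35 % — the
"cells switch off rather than dim" signature.  Forelimb and knockout
conditions do not express the gene.  The per-cluster fold change in
non/low cells shows which populations absorb the loss:

```python
by_cluster = pt.class_proportions(classified, group_by="cluster")
fold = pt.fold_change_nonlow(by_cluster.loc[["WT-HL"]],
                             by_cluster.loc[["PenDel-HL"]])
print(fold.loc[["ICT", "PPP"]].round(3))
```

```
       ref_frac_nonlow  alt_frac_nonlow   fold
group
ICT              0.137            0.470  3.431
PPP              0.121            0.269  2.219
```

The irregular-connective-tissue (ICT) and proximal-progenitor (PPP)
clusters show ~3.4- and ~2.2-fold increases in silent cells — the two
proximal clusters the deletion hits hardest under the default study
design.

A shell session covers the same ground:

```bash
pitx1tools simulate-cells --seed 1 --out cells.tsv
pitx1tools classify --cells cells.tsv --out classified.tsv
pitx1tools proportions --cells classified.tsv --group-by cluster
pitx1tools simulate-contacts --seed 2 --out pairs.tsv
pitx1tools v4c --pairs pairs.tsv --preset pitx1-mm9 --out profile.bedgraph
```

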