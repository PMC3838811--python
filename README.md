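# phenorank

Multi-label prediction of gene deletion phenotypes from precomputed
functional-enrichment features.

Knocking out a gene and observing the phenotype is the classical way to
probe gene function, but it is slow, costly, and sometimes impossible
(lethal deletions, ethical limits in higher organisms). `phenorank`
implements a computational alternative for the budding-yeast setting:
proteins are described by numeric GO / KEGG pathway enrichment scores and
annotated with one or more of q deletion-phenotype categories (conditional
phenotypes, cell cycle defects, mating/sporulation defects, ...). Because a
protein typically carries several phenotype tags, the predictor does not
output a single class but a complete ranking of all q phenotypes for each
query protein.

## Method

The pipeline, in the order it runs:

1. **Standardization.** Every feature column is z-scored,
   `U_ij = (u_ij − u_j) / T_j`, with the population mean `u_j` and std `T_j`
   of feature j; constant features are dropped.
2. **Correlation pre-filter.** Feature j is kept iff
   `max_c |Pearson r(X_j, Y_c)| ≥ 0.1` over the q binary phenotype columns
   `Y_c`; weakly label-related features are discarded.
3. **mRMR ranking.** Features are coarsened to three states around
   mean ± σ and ranked by plug-in mutual information (bits): the *MaxRel*
   table sorts by relevance `max_c I(f; Y_c)` alone; the *mRMR* table uses
   the greedy difference criterion
   `argmax_f [ I(f; class) − (1/|S|) Σ_{s∈S} I(f; s) ]`
   to penalize redundancy with the already-selected set S.
4. **kNNA classifier.** For a query protein P, the k training proteins with
   the largest cosine similarity `cos⟨p_x, p_y⟩ = p_x·p_y / (‖p_x‖‖p_y‖)`
   are retrieved with weights `w_1 ≥ … ≥ w_k`, and each phenotype j is
   scored by the weighted vote `S(P⇒j) = Σ_i w_i · t_{p_i,j}`, where
   `t_{p_i,j}` indicates whether neighbor i carries tag j. Sorting the q
   scores descending yields the label ranking.
5. **Evaluation.** Leave-one-out (jackknife): each protein is knocked out
   in turn and predicted from the rest. The order-i accuracy
   `A^i = (1/m) Σ_z t_{z, μ_i(z)}` is the fraction of proteins whose rank-i
   predicted label is among their true labels. For any complete ranking,
   `Σ_i A^i = (total tag assignments)/m` holds exactly — a conservation law
   the test suite exploits.
6. **Incremental feature selection (IFS).** Nested prefixes
   `S_n = {f_1..f_n}` of the ranked feature list are evaluated for every k
   in a grid; the (k, n) cell with the highest A¹ is the operating point.
7. **RPC baseline.** Ranking by pairwise comparison: the q-label problem
   becomes q(q−1)/2 one-vs-one tasks (a protein enters the (a, b) subset iff
   it carries exactly one of the two tags); each trained binary classifier
   casts one vote and labels are ranked by vote count. The binary learner
   is pluggable; the default is a deterministic cosine nearest-centroid.

A synthetic-data module generates benchmark-shaped multi-label datasets
(skewed tag prevalence, mean multiplicity ≈ 1.64 tags/protein, planted
label-informative features) so the whole pipeline is testable without the
original enrichment matrix, which is not redistributable.

## Worked example

```sh
phenorank simulate --out-dir data --n-proteins 120 --n-features 40 \
    --n-informative 6 --q-labels 4 --mean-labels 1.64 \
    --signal 2.5 --noise-sd 1 --seed 7
phenorank preprocess --features data/features.tsv --labels data/labels.tsv \
    --out-features pre.tsv --out-filter filter.tsv
phenorank rank --features pre.tsv --labels data/labels.tsv \
    --out-maxrel maxrel.tsv --out-mrmr mrmr.tsv
phenorank ifs --features pre.tsv --labels data/labels.tsv --ranked mrmr.tsv \
    --k-grid 1:9 --max-n 12 --out-grid grid.tsv --out-plot curves.png
```

which logs, per stage:

```
INFO wrote data (n=120, d=40, q=4)
INFO features: 40 in -> 40 standardized -> 29 kept (threshold 0.1)
INFO ranked 29 features (MaxRel + mRMR)
INFO IFS: best A1=0.9833 at k=9, n=6 (grid 108 cells)
```

Read: of 40 simulated features, 29 survive the 0.1 correlation filter; the
IFS grid over k = 1..9 and feature prefixes n = 1..12 peaks at a first-order
accuracy of 0.9833 using 9 neighbors and the top 6 mRMR features — exactly
the 6 label-informative features planted by the simulator (see
`mrmr.tsv` for the ranked list, `grid.tsv` for every (k, n, A¹..A⁴) cell,
and `curves.png` for one IFS curve per k with the peak annotated).
`phenorank predict` then ranks phenotypes for new query tables and
`phenorank rpc` runs the pairwise-comparison baseline.

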