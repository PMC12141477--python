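# metscreen

Hit calling for **in vivo genome-wide CRISPR knockout screens of metastasis**.

In a transplantation metastasis screen, tumor cells carrying a pooled
knockout library (several sgRNAs per gene, transduced at MOI ~0.3 so that
most cells carry a single guide) grow as a primary tumor in each of several
replicate mice at high per-sgRNA coverage (≥200 cells/sgRNA).  Metastatic
nodules — here the lung, optionally the liver — are sequenced alongside the
matched primary tumor.  Knocking out a **metastasis suppressor** raises a
cell's probability of seeding the lung, so its sgRNAs become *enriched* in
lung metastases relative to the primary tumor of the same mouse.  Because
organ seeding is a tight clonal bottleneck, single comparisons are noisy;
the signal lives in consistency across sgRNAs, replicate mice and cell
lines.  `metscreen` implements that whole inference chain, plus a generative
screen simulator with planted ground truth so every stage is testable
without any sequencing data.

## The model

**Per-sgRNA paired test.** Counts are depth-normalized by median-of-ratios
size factors.  For sgRNA *i* in one mouse, the metastasis count *t_i* is
tested against a negative binomial null with mean `μ_i` (the normalized
primary-tumor abundance, plus a pseudocount of 1) and variance from an
empirical mean–variance law fitted across primary replicates:

    var(μ) = μ + k·μ^b          (size r = μ²/(var−μ); Poisson if var ≤ μ)

giving exact tails `p_high = P(X ≥ t)` (enrichment / positive selection)
and `p_low = P(X ≤ t)` (depletion / negative selection).

**Gene-level α-RRA.** sgRNAs are ranked screen-wide in each direction; a
gene with *m* sgRNAs at sorted fractional ranks `r_1 ≤ … ≤ r_m` scores

    ρ = min over {i : r_i ≤ α} of I_{r_i}(i, m−i+1)

the minimum uniform-order-statistic (regularized incomplete beta) tail over
its top-α sgRNAs (ρ = 1 if none qualifies; α = 0.05 by default).  ρ is
calibrated by a seeded permutation null that reassigns sgRNA ranks to genes
preserving sgRNA counts, with add-one p-values, Benjamini–Hochberg FDR and
deterministic 1-based `neg|rank` / `pos|rank` report ranks.

**Replicate integration.** Of the replicate mice, the *k* = 4 with the
highest lung preference (lung / (lung+liver) metastatic burden) are kept;
each gene's representative value is its smallest FDR-adjusted p across
those mice, reported as an **essentiality score** `−log10(min adj. p)` and
a final rank.  Two cell lines are intersected by significance in both
(concordant genes) and by worst-of-two-lines combined rank (top-k genes in
common).  An alternative analysis keeps genes that act on lung but not
liver colonization: in *every* mouse, `neg|rank(lung) > neg|rank(liver)`
and `pos|rank(lung) < pos|rank(liver)`, with Fisher-combined p across
replicates ranking the passing genes.

**Simulator.** Log-normal plasmid abundances → multinomial founder cells
per mouse → gamma-multiplicative clonal growth → per-cell Bernoulli organ
seeding (planted suppressor genes multiply the seeding probability)
truncated to a bottleneck → metastatic outgrowth → multinomial sequencing.
Fully deterministic given one master seed.

## Worked example

Simulate a 500-gene screen with three planted suppressors — two
lung-specific (`G042`, `G117`, lung effect ×10) and one pan-organ
(`G300`, lung and liver ×10) — then run the main analysis:

```
$ metscreen simulate --config sim.yaml --out screen
wrote simulated screen (500 genes x 4 sgRNAs, 5 mice, coverage 200x) to screen

$ metscreen call --counts screen/counts.tsv --library screen/library.tsv \
    --meta screen/meta.yaml --cell-line SIM1 --select-mice 4 \
    --n-perm 1000 --seed 3 --out results
selected mice: m3, m2, m1, m4
wrote 5 gene reports and the essentiality table to results
```

The essentiality table ranks all three planted suppressors on top — their
smallest adjusted p across the four selected mice (0.125, the permutation
resolution at 1000 permutations after FDR adjustment) beats every
unplanted gene:

```
gene   padj_m3   padj_m2  padj_m1  padj_m4  min_adj_p  essentiality_score  final_rank
G042   0.124875  0.1665   0.1665   0.1665   0.124875   0.903524            1
G117   0.124875  0.1665   0.1665   0.1665   0.124875   0.903524            2
G300   0.124875  0.1665   0.1665   0.1665   0.124875   0.903524            3
```

The lung-vs-liver filter then separates organ specificity: the two
lung-specific genes pass in all five mice with the strongest combined
evidence, while the pan-organ gene `G300` is excluded because its liver
enrichment violates the rank inequalities:

```
$ metscreen filter-lungliver --counts screen/counts.tsv ... --out results
6 of 500 genes pass in all 5 mice; table written to results

gene    combined_p    comprehensive_rank
G042    1.407e-09     1
G117    1.407e-09     2
G255    3.881e-02     3
```

Small bench formulas are exposed the same way, e.g. an RNAscope H-score
from binned dots/cell counts (`0·%bin0 + 1·%bin1 + … + 4·%bin4`):

```
$ metscreen hscore --bins 10,20,30,20,20
220
```

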