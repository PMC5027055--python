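# trendnet

Analysis toolkit for short time-course expression studies of long
noncoding RNAs (LncRNAs) and mRNAs — the design used to profile gene
expression over days 0, 1, 3, 7 and 21 after an intervention such as a
contusion spinal cord injury. It is aimed at computational biologists
who have a transcript × sample matrix of log2 intensities with
LncRNA/mRNA labels and want the full downstream chain as reusable,
tested code:

1. **Differential calling vs day 0** — per gene and time point,
   log2FC = x̄ₜ − x̄₀ with a pooled-variance t-test, BH-adjusted within
   each comparison; selected when |log2FC| ≥ 1 and q ≤ 0.05; union set
   across time points and hierarchical heat-map ordering.
2. **Series test of cluster (STC)** — every discrete trend profile with
   unit steps sₜ ∈ {−1, 0, +1} over T points (3⁴ − 1 = 80 profiles for
   T = 5 with the flat profile excluded); each gene assigned to the
   profile maximising Pearson r with its anchored trend; per-profile
   counts tested against a permutation null where each gene's time
   points are shuffled, with p = P(X ≥ k), X ~ Binomial(N, e/N), and BH
   adjustment across profiles (significant at adj_p < 0.05).
3. **Term enrichment** — two-sided Fisher exact and χ² tests on the
   2×2 list/term table against the array background, BH q-values,
   significance gate p < 10⁻⁴; GMT input.
4. **Coexpression network** — Pearson r over per-gene time-mean
   vectors; signed edges where |r| ≥ 0.997; degree, K-core and
   clustering coefficient per node; hub ranking.
5. **qPCR quantification** — 2^−ΔΔCT relative to day 0 with a reference
   gene, t-tests on replicate ΔCt values, and concordance against the
   array fold changes.

A seeded synthetic-study generator with full ground truth (planted
trends, coexpressed LncRNA–mRNA pairs, enriched terms, Ct tables)
drives the test suite, so every stage is verifiable without downloading
any data. See `docs/methods.md` for the models and conventions.

## Worked example

```python
from trendnet import (SimulationConfig, generate_timecourse,
                      DifferentialExpressionCaller, TrendProfileClusterer,
                      CoexpressionNetworkBuilder)

cfg = SimulationConfig(seed=7)           # 200 LncRNA + 800 mRNA, 5 time points x 3 reps
matrix, truth = generate_timecourse(cfg)

de = DifferentialExpressionCaller(fc_threshold=2.0, fdr_threshold=0.05).fit(matrix)
print(f"union set: {len(de.union_)} genes")

stc = TrendProfileClusterer(n_permutations=1000, random_state=7).fit(
    matrix.restrict(de.union_))
print(stc.significance_[stc.significance_.significant].head())

net = CoexpressionNetworkBuilder(threshold=0.997).fit(matrix, list(de.union_))
print(f"network: {net.graph_.number_of_nodes()} nodes, "
      f"{net.graph_.number_of_edges()} edges; hubs: {net.hubs(3)}")
```

prints

```
union set: 275 genes
 profile_id  genes_assigned  genes_expected             p         adj_p  significant
         21              43           8.850  1.655730e-17  3.311459e-16         True
         53              86           1.781 1.446495e-116 5.785981e-115         True
         67              50           5.719  2.039804e-31  5.439477e-30         True
         70              95           1.666 3.465839e-136 2.772671e-134         True
network: 221 nodes, 764 edges; hubs: ['LNC00141', 'LNC00076', 'LNC00184']
```

275 of the 1000 simulated genes pass the fold-change/FDR selection
(the generator planted 300 trended genes at amplitude 1.0 — genes whose
profile only reaches ±1 log2 unit sit at the calling boundary). Four
trend profiles hold far more genes than their permutation expectation
(e.g. profile 70: 95 genes observed vs 1.7 expected, adj_p ≈ 3·10⁻¹³⁴)
— these are the planted trend clusters. At |r| ≥ 0.997 the
cross-biotype network recovers the planted coexpressed pairs, and the
hub ranking surfaces the LncRNAs with the highest core numbers.

The same pipeline runs from the shell:

```sh
trendnet run --out-dir run1 --seed 7          # simulate + all stages
trendnet diffexpr --matrix run1/expression.tsv --fc 2 --fdr 0.05 --out-dir de
trendnet stc --matrix run1/expression.tsv --genes de/union.txt \
             --permutations 1000 --seed 11 --out-dir stc
```

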