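# karyohybrid

Identifying reciprocal natural plant hybrids — and orienting their crosses —
from two independent lines of evidence:

1. **Nuclear karyotype additivity.** A diploid with per-type chromosome
   counts all even produces balanced haploid gametes by meiotic halving; an
   F1 complement is the union of one gamete from each parent. If an observed
   complement (e.g. `2n = 18 = 4m + 6st + 5t + 3T`) equals that union for a
   candidate parent pair (`2n = 22 = 10t + 12st` and `2n = 14 = 8m + 6T`),
   the pair explains the hybrid's nuclear genome — but additivity alone
   cannot say which parent was the seed parent.
2. **Maternal plastome inheritance.** The chloroplast genome is transmitted
   by the seed (♀) parent. Calling substitutions and short indels of each
   taxon against a shared reference plastome and counting shared SNP sites
   identifies the maternal parent; the additivity partner becomes the
   pollen (♂) donor. Reciprocal hybrids share a predicted nuclear karyotype
   but carry different maternal plastomes.

The package implements the full desk-scale pipeline around that argument:

* **karyotype** — centromere-position classification from arm ratios
  (M/m/sm/st/t/T), karyotype formulas, TCL, the longest/shortest ratio L/S,
  the Romero Zarco asymmetry indices A1 = 1 − mean(b/B) over homolog pairs
  and A2 = s/x̄ of chromosome lengths, and the Stebbins two-character
  asymmetry type;
* **hybrid** — balanced gametes, F1 prediction, additivity testing and
  parent-pair screening over a candidate panel;
* **phenetics** — z-scored trait matrices, average Euclidean distances
  d(i,j) = √(Σₖ(x_ik − x_jk)²/p) and UPGMA dendrograms (Newick output);
* **cp_structure** — exact inverted-repeat detection on circular plastomes,
  LSC/IRb/SSC/IRa partition, GC content and junction-gene spans;
* **cp_variation** — anchor-chained collinear variant calling (unique
  k-mer seeds + global alignment of gap segments, indels left-aligned),
  shared-SNP-site counting, MISA-style SSR scanning and catalogue diffing;
* **parentage** — maternal ranking plus additivity combined into a
  ♀ × ♂ cross report with a margin-based confidence flag;
* **simulate** — seeded generators for all of the above, so every stage is
  testable without downloading anything.

## Worked example

Everything below is generated; no external data needed.

```sh
karyohybrid simulate trio --seed 1 --maternal parentA --out trio
karyohybrid run --dir trio --out report
# parentA (♀) × parentB (♂)
```

The simulated trio contains a reference plastome, two diverged parents, a
hybrid carrying parentA's plastome plus a few private mutations, and
karyotype measurement tables for parent-like diploids and their F1. The
pipeline report (`report/report.json`) shows both evidence lines agreeing:

```text
cross: parentA (♀) × parentB (♂) | confident: True
additivity residual: {'T': 0, 'm': 0, 'st': 0, 't': 0}
ranking: [('parentA', 8), ('parentB', 0)]
hybrid karyotype: 2n = 18 = 4m + 6st + 5t + 3T 3B
```

The hybrid shares 8 SNP sites with parentA and none with parentB (margin
8 → parentA is maternal), and its summarized complement is exactly the
balanced-gamete union of the two parents (all residuals zero).

The additivity check alone, on published-style formulas:

```sh
karyohybrid hybrid-test \
    --observed "2n = 18 = 4m + 6st + 5t + 3T" \
    --parents  "2n = 2x = 22 = 10t + 12st" "2n = 14 = 8m + 6T"
```

```json
{"consistent": true,
 "predicted": {"t": 5, "st": 6, "m": 4, "T": 3},
 "residual":  {"m": 0, "st": 0, "t": 0, "T": 0}}
```

meaning the two parental gametes (n = 11 = 5t + 6st and n = 7 = 4m + 3T)
unite into exactly the observed 18-chromosome complement.

Other subcommands: `karyotype` (summaries from arm-measurement TSVs),
`phenetics` (UPGMA from trait tables), `cp-structure` (quadripartite
partition + junction genes), `cp-compare` (VCF + variant counts), `ssr`
(SSR catalogue).

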