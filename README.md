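# famnet

Family-based gene coexpression network analysis for quantitative traits.

When expression data come from a small number of large pedigrees,
standard weighted coexpression network analysis is on shaky ground:
relatives are not independent samples, and large between-family
variation can create spurious module–trait associations. `famnet`
implements a meta-analytic alternative — build one signed coexpression
network *per family*, test each family's module eigengenes against the
trait with a kinship-aware mixed model, combine the family-specific
modules into a common gene set by highest-overlap matching and
intersection/union, and test the resulting family eigengene jointly
across all pedigrees. The package also provides the two whole-sample
baselines (networks on raw and on mixed-model-decorrelated expression)
and a per-probe mixed-model scan, so the approaches can be compared on
the same data.

## The model

Association tests use the variance-components mixed model

    Y_ij = mu + beta * Z_ij + u_ij + v_i + e_ij

for individual *j* in family *i*, where `Z` is a probe or module
eigengene, `u ~ N(0, sigma_g^2 * 2K)` is the additive polygenic effect
(`K` = pedigree kinship matrix), `v ~ N(0, sigma_v^2)` a shared
family-environment effect, and `e` iid noise. Variance components are
estimated by REML; `beta` is Wald-tested. Networks are signed:
correlation is the biweight midcorrelation, adjacency
`a_lk = |0.5 + 0.5 * cor(x_l, x_k)|^gamma`, modules come from
average-linkage clustering of the topological-overlap dissimilarity
with an adaptive tree cut, and each module is summarized by its
eigengene (first principal component of the standardized module
expression). Probe heritability `h2 = sigma_g^2 / (sigma_g^2 +
sigma_v^2 + sigma_e^2)` supports restriction to the most heritable
probes. Because the family data this design targets are
access-restricted, a first-class simulator generates multi-family
pedigrees, modular family-structured expression, and causal plus null
traits for every stage. See `docs/methods.md` for details.

## Worked example

Simulate a 5-family study (40 members each, 300 probes, a shared
trait-associated 60-gene module) and run the family approach:

```bash
famnet simulate --seed 7 --config my_scenario.json --out demo/
famnet run --expr demo/expr.tsv --ped demo/ped.txt --pheno demo/pheno.tsv \
    --trait SBP --mode family --min-module-size 20 --seed 1 --out demo_run/
```

`demo_run/family_summary.json` then reads (abridged):

```json
{
  "top_family": "F2",
  "top_module": "module1",
  "chosen_set": "intersection",
  "intersection_size": 57,
  "union_size": 114,
  "variance_explained": {"F1": 0.42, "F2": 0.40, "F3": 0.36,
                         "F4": 0.40, "F5": 0.34},
  "joint": {"beta": 0.378, "se": 0.145, "p": 0.0089}
}
```

Reading this: the most trait-associated module across the five
family-specific networks was `module1` in family F2 (within-family
p = 0.0053, Bonferroni-significant across the eight module tests, see
`associations_family.tsv`). Matching that module into every family's
network and intersecting gives a 57-gene common core (the planted
module had 60 genes); the intersection eigengene explains 34–42 % of
that gene set's variance in every family, more than the 114-gene union
candidate, so it defines the family eigengene E_F. Tested jointly
across all 200 individuals with the full kinship + family-environment
model, E_F associates with the simulated blood-pressure trait at
beta = 0.378 (se 0.145, p = 0.0089).

Other modes: `--mode naive`, `--mode naive-decor`, `--mode
single-probe`, or `--mode all`; `famnet networks` builds a network
without any trait testing. Every run writes TSV tables, a GMT file of
the matched/common gene sets, and a `manifest.json` with checksums —
identical seeds and inputs reproduce every file byte for byte.

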