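# pstfst

Divergence analysis for natural populations genotyped with **dominant
markers** (AFLP-style band presence/absence) and measured for
**quantitative traits**: is the phenotypic differentiation among
populations larger than neutral genetic drift can explain?

The package targets the standard workflow of P_ST–F_ST comparison
studies in plants and other non-model organisms:

1. estimate allele frequencies from band-absence counts (`√(x/n)` or a
   Bayesian estimator with a non-uniform Beta prior fitted across loci),
2. partition Nei gene diversity into within- (Hw) and among-population
   (Hb) components, giving **F_ST = Hb/(Hw+Hb)** with a permutation test,
3. screen loci for selection with a per-locus F_ST scan against a
   simulated Balding–Nichols neutral null and keep the neutral subset,
4. quantify trait divergence with

   **P_ST = (c/h² σ_B²) / (c/h² σ_B² + 2 σ_W²)**

   from one-way between/within mean squares (σ_B² ≡ MSB, σ_W² ≡ MSW),
   with 95% percentile-bootstrap confidence intervals, P_ST-vs-c/h²
   sensitivity curves, and the **critical c/h²** decision rule
   (≤ 0.5 strong, < 1 weak evidence for diversifying selection),
5. test trait differences nonparametrically (tie-corrected
   Kruskal–Wallis, Dunn post hoc),
6. relate divergence to geography and climate with haversine/Euclidean
   distance matrices, Mantel and partial Mantel permutation tests, and
   redundancy analysis (RDA) with forward selection.

A synthetic-data module generates marker, trait, site and climate tables
with known F_ST, known expected P_ST and geographic climate gradients,
so every stage is testable without any external download; the published
summary tables the package is validated against ship as typed fixtures
(`make_paper_fixture()`).

## Worked example

P_ST for seven morphological traits recomputed from the packaged
per-population summary table (11 populations, N = 74), compared against
the neutral F_ST of 0.329, plus the isolation-by-distance test from the
packaged site coordinates and pairwise F_ST matrix:

```python
import pstfst as pf

summary, sites, pairwise = pf.make_paper_fixture()
fst = 0.329
for trait in summary.trait_names:
    est = pf.pst_bootstrap(summary, trait, c_over_h2=0.5, n_boot=9999, seed=42)
    est.critical_ratio = pf.critical_c_ratio(None, trait, fst, estimate=est)
    print(trait, round(est.pst, 3), (round(est.ci_low, 3), round(est.ci_high, 3)),
          round(est.critical_ratio, 3), pf.classify_selection(est, fst))

geo = pf.geographic_distance_matrix(sites)
gen = pf.DistanceMatrix(pairwise.populations, pairwise.matrix, "fst")
res = pf.mantel(geo, gen, n_perm=9999, seed=42)
print(f"Mantel r = {res.r:.3f}, p = {res.p_value:.4f}")
```

prints

```text
RAL 0.556 (0.43, 0.752) 0.325 diversifying_strong
PLB 0.668 (0.561, 0.804) 0.192 diversifying_strong
PLA 0.536 (0.416, 0.723) 0.345 diversifying_strong
SSL 0.58 (0.449, 0.762) 0.301 diversifying_strong
FPL 0.476 (0.374, 0.689) 0.411 diversifying_strong
FRL 0.871 (0.808, 0.924) 0.059 diversifying_strong
FRW 0.869 (0.81, 0.923) 0.058 diversifying_strong
Mantel r = 0.453, p = 0.0030
```

Every trait's P_ST point estimate exceeds F_ST = 0.329 and the lower CI
bound clears it at a critical c/h² below 0.5 — evidence for diversifying
selection that survives even pessimistic assumptions about how much of
the between-population variance is additive. The fruit traits (FRW, FRL)
carry the strongest signal. The Mantel test shows genetic divergence
increasing with geographic distance (isolation by distance).

A command-line interface mirrors the library
(`pstfst fst|outliers|pst|kw|mantel|rda|simulate|report`), e.g.

```sh
pstfst simulate --out data/ --seed 1
pstfst fst --markers data/markers.csv --nperm 1000 --seed 1 --out fst.json
```

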