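# steppescan

Detecting and dating directional gene flow from a source region into a set
of focal populations, from identity-by-descent (IBD) segment sharing,
f3 admixture tests and admixture-LD / ancestry-tract dating — with
synthetic-data generators that exercise every step against known ground
truth.

The package is aimed at population geneticists who have (1) a table of IBD
segments between individuals (fastIBD-style post-processed output), (2)
population metadata with coordinates and geographic-neighbor sets, and (3)
diploid genotypes with a genetic map, and who want to ask: *do my focal
populations share more recent ancestry with a candidate source region than
their geographic neighbors do — and when did that gene flow happen?*

## What it computes

* **IBD sharing statistic** — per population pair and segment-length bin
  (default 1–2 … 5–6 cM), total shared cM divided by the number of
  individual pairs.
* **Distance decay** — Pearson correlation between `−ln(S)` and geodesic
  distance (haversine, R = 6371 km), both max-standardized; sharing decays
  as `β e^{−d/λ}` under isolation by distance, so `−ln S` is linear in d.
* **Subtraction–accumulation scan** — for each focal population f,
  `diff_f = vector(f) − vector(pooled neighbors of f)` over all reference
  populations; `A_ref = Σ_f diff_f[ref]` accumulates *correlated* excess
  sharing, flagged above the 0.90 sample quantile, with a
  random-neighbor null.
* **Permutation test** — pooled-neighbor pseudo-populations (default
  10,000 draws); `p = #{permuted ≥ observed}/n_perm`.
* **f3 admixture test** — `f3(T; A, B) = mean[(ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n_c−1)]`
  with weighted block-jackknife SE over 5 cM windows; admixture is called at
  Z < −1.64 (one-tailed) or the Bonferroni cut `Φ⁻¹(α/n_tests)`
  (−4.89 for α = 0.05 over 97,548 trios).
* **Admixture dating** — weighted-LD decay `y(d) = A e^{−g d} + c` fit over
  0.5–30 cM, ancestry-tract inversion `ĝ = 1/(L̄(1−α))`, single-path IBD
  length conversion `E[L] = 100/(2g)` cM, calendar anchoring
  `year = 2000 − 30 g`, and an RMSE/bias benchmark harness over simulated
  scenarios.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import steppescan as ss

# --- a synthetic study: 4 focal populations, their neighbors, one source ---
records = [("SRC", 50.0, 95.0, "source")]
neighbor_sets = {}
for k in range(4):
    records.append((f"F{k}", 45.0, 40.0 + 6 * k, "focal"))
    ns = [f"N{k}_0", f"N{k}_1"]
    for j, n in enumerate(ns):
        records.append((n, 45.5, 40.3 + 6 * k + 0.4 * j, "neighbor"))
    neighbor_sets[f"F{k}"] = ns
for r in range(5):
    records.append((f"R{r}", 42.0, 35.0 + 9 * r, "reference"))
pops = ss.PopulationTable.from_records(records, neighbor_sets)
sizes = {p: 25 for p in pops.population_ids}

config = ss.SharingSimConfig(
    populations=pops, sample_sizes=sizes,
    baseline_rate_cM=1.0, decay_scale_km=2000.0,
    gene_flow_edges=[ss.GeneFlowEdge("SRC", f"F{k}", 2.0) for k in range(4)],
    bins=[ss.LengthBin(1, 2)], seed=42,
)
segments, truth = ss.simulate_sharing_network(config)
S = ss.sharing_matrix(segments, pops, config.bins, sizes)

scan = ss.ScanConfig(focal_ids=[f"F{k}" for k in range(4)],
                     neighbor_sets=neighbor_sets, bin=config.bins[0], seed=1)
result = ss.subtract_accumulate(S, scan)
print("flagged:", result.flagged)
i = result.reference_ids.index("SRC")
print(f"A_SRC = {result.accumulated[i]:.2f} cM (threshold {result.threshold:.2f})")

res = ss.excess_sharing_pvalue(segments, "F0", "SRC", neighbor_sets["F0"],
                               config.bins[0], config.sample_map(),
                               n_perm=10000, seed=2)
print(f"permutation p = {res.p_value} (min resolvable {res.min_p})")

cfg = ss.AdmixtureSimConfig(g=20, alpha=0.5, seed=3)
geno, tracts = ss.simulate_admixed_haplotypes(cfg)
est = ss.date_admixture_ld(geno, "admixed", "source1", "source2")
print(f"weighted-LD: g = {est.g_hat:.1f} (95% CI {est.ci_low:.1f}-{est.ci_high:.1f}), "
      f"calendar year {est.calendar_year:.0f}")
```

Output:

```
flagged: ['SRC', 'N1_1']
A_SRC = 7.78 cM (threshold 0.23)
permutation p = 0.0 (min resolvable 0.0001)
weighted-LD: g = 18.8 (95% CI 17.1-20.5), calendar year 1437
```

Reading it: the source accumulates `A_SRC ≈ 7.8 cM ≈ 4 focal × 2 cM`
injected excess, far above the 0.90-quantile threshold (the scan always
flags the top decile, so an occasional neighbor rides along); the
permutation test cannot produce the focal population's excess sharing from
its pooled neighbors in any of 10,000 draws (p below the 1/10,000
resolution); and the weighted-LD decay dates the simulated g = 20 pulse to
18.8 generations, i.e. a calendar date around 1437 CE under 30-year
generations anchored at 2000 CE.

## Command line

The same steps are exposed as a thin CLI:

```sh
steppescan validate  --in pops.tsv --format populations
steppescan simulate sharing --config sim.yaml --seed 5 --out-dir sim/
steppescan sharing   --segments sim/segments.tsv --pops pops.tsv \
                     --sample-map sim/sample_map.tsv --bins 1,2 --out S.tsv
steppescan decay     --sharing S.tsv --pops pops.tsv --out decay.tsv
steppescan scan      --sharing S.tsv --config scan.yaml --bin 1-2 \
                     --null-replicates 10 --seed 7 --out scan/
steppescan permtest  --segments ... --focal F0 --sources SRC --n-perm 10000 ...
steppescan f3        --dosages d.tsv --snps snps.tsv --sample-map sm.tsv --out f3.tsv
steppescan date      --dosages d.tsv --snps snps.tsv --sample-map sm.tsv \
                     --admixed admixed --ref1 source1 --ref2 source2 --out date.tsv
steppescan benchmark --scenarios 5,10,20,30,40,50,60 --reps 10 \
                     --estimator tracts --seed 3 --out bench.tsv
```

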