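# betafacets

Covariation of the **taxonomic** and **functional** facets of β-diversity
across presence/absence assemblages, with partitioning into **turnover** and
**nestedness-resultant** components and simulation of extinction scenarios.
Built for the kind of question faced in freshwater-fish conservation:
as exotic species spread and threatened natives disappear, do assemblages
become more similar (biotic homogenization), and do the taxonomic and
functional dimensions of that change move together?

## The statistics

For a pair of assemblages with `a` shared species and `b`, `c` species unique
to each side, the taxonomic indices are the Jaccard-family partition

```
TD_beta = (b + c) / (a + b + c)
TD_tur  = 2 min(b,c) / (a + 2 min(b,c))
TD_nes  = TD_beta - TD_tur  =  (|b - c| / (a+b+c)) * (a / (a + 2 min(b,c)))
```

The functional analogues replace species counts with convex-hull volumes in a
trait space — species are embedded by PCoA (first `m = 3` axes) of the Gower
distance over five life-history traits, and each assemblage is the convex
hull of its species' coordinates.  With hull volumes `V1`, `V2` and shared
volume `Vi = V(hull1 ∩ hull2)`,

```
FD_beta = (V1 + V2 - 2 Vi) / (V1 + V2 - Vi)
FD_tur  = (2 min(V1,V2) - 2 Vi) / (2 min(V1,V2) - Vi)
FD_nes  = FD_beta - FD_tur
```

Pairwise intersections are computed exactly (pooled facet halfspaces, a
Chebyshev-centre linear program certifying an interior point, then vertex
enumeration), not by sampling.

Changes between compositional scenarios (historical → current → hypothetical
futures in which Endangered, then Endangered + Vulnerable natives go extinct)
are summarised per basin pair as Δ values; the covariation of ΔTD and ΔFD is
measured by Pearson *r* and the OLS slope *m*, with significance from Monte
Carlo randomization (the taxonomic vector permuted, 1,000 times by default).

## Worked example

The built-in generator produces study-like synthetic datasets: 20 basins on
a latitudinal gradient, 30 natives with narrow right-skewed ranges (14
Endangered, 11 Vulnerable, one extinct), and 28 exotics including a
widespread, functionally similar salmonid-like cluster.

```python
import betafacets as bf

cfg = bf.paper_default_config(seed=1)
scenarios, traits, meta = bf.generate_dataset(cfg)
report = bf.run_full_analysis(scenarios, traits, meta, n_perm=1000, seed=1)

for facet in ("taxonomic", "functional"):
    for scen in ("historical", "current"):
        m, sd = report.summaries[(facet, scen)]["beta"]
        print(f"{facet:10s} {scen:10s} beta = {m:.3f} +/- {sd:.3f}")
pc = report.percent_changes
print(f"delta TD_beta = {pc[('taxonomic','current','beta')]:+.1f}%  "
      f"delta FD_beta = {pc[('functional','current','beta')]:+.1f}%")
blk = report.regressions[("current", "beta")]
print(f"r = {blk.fit.r:.3f}  m = {blk.fit.slope:.3f}  "
      f"perm p = {blk.perm_r.p_two_sided:.4f}")
q = report.quadrants[("current", "beta")]
print(f"joint decline: {q.neg_neg:.1f}% of basin pairs")
```

prints

```
taxonomic  historical beta = 0.656 +/- 0.266
taxonomic  current    beta = 0.648 +/- 0.148
functional historical beta = 0.759 +/- 0.285
functional current    beta = 0.623 +/- 0.196
delta TD_beta = -1.3%  delta FD_beta = -18.0%
r = 0.474  m = 0.584  perm p = 0.0010
joint decline: 62.1% of basin pairs
```

Both facets of β-diversity fall from the historical to the current scenario
(homogenization), the functional facet falls much harder, the per-pair
changes are positively correlated, and most basin pairs decline jointly.

A `betafacets` command-line tool wraps the same pipeline:
`simulate` (synthetic data), `convert` (bracket-notation occurrence tables →
per-scenario CSVs), `scenarios` (status-driven extinction futures),
`taxbeta` / `funbeta` (pairwise partitions) and `analyze` (full report).

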