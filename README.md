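# ripopgen

Population-genetic analysis of mixed-mating plants under congener
competition: a conservative parent–offspring outcrossing classifier with
a binomial-logit GLMM stage, per-population diversity/inbreeding indices,
three selfing-rate estimators, effective-population-size estimators,
pairwise differentiation with a permutation GLM, and a bootstrap
framework for comparing indices between sympatric and allopatric
population groups. A forward simulator of partial-selfing
metapopulations makes every stage testable without field data.

## Package layout

| module | contents |
| --- | --- |
| `ripopgen.genotype_io` | `GenotypeMatrix`, `PopulationSet`, `SeedFamily`, `PlotSurvey`; GenAlEx / STRUCTURE / long-CSV readers and writers |
| `ripopgen.synthetic_data` | partial-selfing Wright–Fisher simulator (single population and island metapopulation), seed-family and plot-survey generators with known truth |
| `ripopgen.diversity` | allele frequencies, H_O, Nei's unbiased H_E, rarefied allelic richness, rare-allele counts, Weir–Cockerham F_IS |
| `ripopgen.mating_system` | S_F = 2F/(1+F), identity-disequilibrium (g2) selfing estimator, maximum-likelihood selfing estimator, maternal allele-exclusion seed classifier, plot outcrossing rates, outcrossing GLMM |
| `ripopgen.effective_size` | LD-based Ne (Burrows r² with bias correction, parametric CI) and molecular co-ancestry Ne |
| `ripopgen.differentiation` | pairwise Jost's D, Euclidean distances, permutation GLM on pair type + distance, delta-K summary of clustering runs |
| `ripopgen.inference` | bootstrap group tests with directional alternatives, bootstrap power analysis, consolidated comparison report |
| `ripopgen.cli_pipeline` | `ripopgen` CLI and the end-to-end `run-all` orchestration |

## Command-line interface

```sh
ripopgen simulate --config sim.yaml --out simdir      # synthetic data + truth JSON
ripopgen convert in.csv out.str --from long --to structure
ripopgen indices genotypes.csv --out indices.csv      # A, AR, RA, H_O, H_E, F_IS
ripopgen selfing genotypes.csv --out selfing.csv      # S_F, S_g2, S_ML
ripopgen ne genotypes.csv --out ne.csv                # Ne_LD (with CI), Ne_Cn
ripopgen outcross families.csv --out oc               # seed calls + plot rates
ripopgen glmm plots.csv --out glmm.json               # outcrossing GLMM
ripopgen diff genotypes.csv --out diff                # Jost's D + permutation GLM
ripopgen evanno lnp.csv --out deltak.csv              # delta-K from (K, replicate, lnP)
ripopgen compare --indices indices.csv --ne ne.csv --selfing selfing.csv --out report.csv
ripopgen run-all --config analysis.yaml --out results/
```

`run-all` accepts a YAML config with either an `input:` block
(`path`, `format`) or a `simulate:` block (forward-simulator parameters),
plus `rarefaction_g`, `p_crit`, `B`, `n_perm`, `alpha` and `seed`; it
writes every table plus a `manifest.json` with seeds and output
checksums, and reruns with the same seed are byte-identical.

Genotype formats: GenAlEx codominant CSV (missing allele code 0),
STRUCTURE one-/two-row text (missing code −9) and a tidy long CSV
(`population,pop_type,x_km,y_km,sample_year,individual,locus,allele1,allele2`)
which is the only dialect carrying population metadata. Coordinates are
planar km; `genotype_io.project_lonlat_km` provides an equirectangular
pre-projection for lon/lat input.

## Notes and caveats

- The outcrossing classifier is deliberately conservative: a seed is
  called outcrossed only when it carries an allele absent from its
  mother, so outcrossing is never overestimated on error-free
  genotypes; selfing counts can absorb undetected outcrosses.
- Selfing-rate indices cannot distinguish autonomous from
  pollinator-mediated selfing.
- Both Ne estimators assume random mating; a warning is emitted when
  F_IS > 0.5 (estimates are then biased low, mirroring standard usage).
- Rare alleles use the pooled-across-populations frequency reading of
  the <1% rule; a per-population reading is not implemented.
- Jost's D combines loci by arithmetic mean by default; a harmonic-mean
  variant is available (`combine="harmonic"`).
- The permutation GLM permutes pairwise rows, inheriting the usual
  non-independence caveat of pairwise matrices.
- Sibship-assignment quantities (selfing rate, Ne) are not
  re-implemented; externally computed per-population values can be
  merged into the comparison report via
  `inference.read_external_index_csv` / `ripopgen compare --external`.
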