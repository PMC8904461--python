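# ssrid

SSR (microsatellite) individual-identification and population-genetics
toolkit for diploid genotype data.

Given a genotype matrix (individuals × loci, two integer allele calls per
cell, population labels) the package computes:

- **Per-locus statistics** — allele count (A), observed/expected
  heterozygosity (Ho, He, unbiased uHe), polymorphism information content
  (PIC), power of discrimination (PD = 1 − Σ genotype-freq², on observed
  genotype frequencies), probability of identity (PI = 1 − PD), and
  Hardy–Weinberg tests (chi-square or seeded Monte-Carlo exact).
- **Linkage structure** — pairwise genotypic LD via a permutation G-test,
  linkage groups as connected components (or pairwise cliques) of the
  significant-pair graph, and a minimum-PI representative per group.
- **Forensic accumulation** — PI-sorted cumulative probability of identity
  (CPI) and power of discrimination (CPD = 1 − CPI) over non-linked loci,
  confidence levels CL = (1 − CPI)^N, and the maximum identifiable
  population size at target confidence levels.
- **Population structure** — per-population A/Ho/He and Fis = 1 − Ho/He,
  pairwise Fst (Nei-style (Ht−Hs)/Ht by default, Weir–Cockerham θ as an
  option), island-model gene flow Nm = (1 − Fst)/(4 Fst), and Evanno ΔK
  post-processing of clustering-run log-likelihood tables.
- **Provenance assignment** — frequency-method genotype likelihoods with
  leave-one-out self-assignment and per-population accuracy.
- **Synthetic data** — a Balding–Nichols genotype simulator with target
  Fst/Fis, perfectly linked locus groups, null alleles and missing data,
  used throughout the test suite for parameter-recovery checks.

Supported text formats: GenAlEx codominant CSV (missing code `0`), Genepop
with 2/3-digit coding (`000` missing), and two-row STRUCTURE files (`-9`
missing). All statistics are complete-case per locus.

## Command-line usage

```sh
# generate the canonical synthetic fixture (4 pops, 92 individuals, 36 loci)
ssrid simulate --out sim.csv --truth truth.json --seed 42

# per-locus statistics table
ssrid locus-stats --in sim.csv --format genalex --hwe chi2 --out locus.csv

# LD testing and linkage groups
ssrid linkage --in sim.csv --alpha 0.001 --reps 10000 --seed 42

# cumulative CPI/CPD and identifiable-N profile
ssrid forensic --in sim.csv --cl 0.95 --cl 0.99 --cl 0.9999

# population-level statistics
ssrid popstats --in sim.csv
ssrid fst --in sim.csv
ssrid deltak --in lnp.csv            # CSV with columns K, run, lnP
ssrid assign --in sim.csv --loo --zero-freq 0.01

# everything at once, with a machine-readable JSON report
ssrid run-all --in sim.csv --seed 42 --outdir results/
```

Every stochastic step (permutation tests, Monte-Carlo HWE, simulation)
requires an explicit seed; a re-run with the same inputs and seeds
reproduces every number exactly.

## Library example

```python
from ssrid import (canonical_config, simulate_dataset, summarize_loci,
                   cumulative_profile)
from ssrid.linkage import pairwise_ld, linkage_groups, select_representatives

matrix, truth = simulate_dataset(canonical_config(seed=1))
summaries = summarize_loci(matrix)
pi_of = {s.locus_id: s.PI for s in summaries}

p = pairwise_ld(matrix, reps=10_000, seed=1)
structure = select_representatives(linkage_groups(p, matrix.locus_ids), pi_of)

profile = cumulative_profile({l: pi_of[l] for l in structure.representatives})
print(profile.to_frame())
```
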