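# sundiv

Diversity partitioning for repeated forest-census plot networks: Hill-number
alpha / beta (representativeness) / gamma decomposition of metacommunities,
zone-wise composition- and range-change indices between censuses, and
ordinary-kriged diversity surfaces with cross-validation.  Built for
long-term permanent-sample-plot data of the kind collected in the Sundarbans
mangrove network (110 plots, three salinity zones, four censuses), with a
seeded synthetic-data generator as a test substrate.

## Who it is for

Community ecologists tracking *biotic homogenization* — the loss of
between-site compositional differences as generalists expand and specialists
decline — and anyone partitioning abundance data into subcommunity-level
effective-species measures (the machinery is the same Hill-number framework
used for microbiome alpha/beta diversity).

## The measures

A metacommunity is a species x subcommunity relative-abundance matrix `p`
(grand sum 1), with subcommunity weights `w_j = Σ_s p_sj`, column
distributions `p̂_sj = p_sj / w_j`, and pooled frequencies `P_s = Σ_j p_sj`.
At viewpoint parameter `q ≥ 0` (q=0 richness, q=1 Shannon-exponential, q=2
inverse-Simpson-related):

* `ᾱ_j = [Σ_s p̂_sj^q]^(1/(1−q))` — effective species count of subcommunity
  j in isolation;
* `ρ̄_j = M_{1−q}(p̂_·j, P_s/p̂_sj)` — representativeness: 1 iff j's
  composition mirrors the pooled metacommunity, never below `w_j`;
* `γ_j = M_{1−q}(p̂_·j, 1/P_s)` — j's per-individual contribution to the
  pooled diversity; the order-(1−q) weighted mean of the `γ_j` equals the
  metacommunity gamma `[Σ_s P_s^q]^(1/(1−q))` exactly.

Rising ρ̄ across censuses = subcommunities converging in composition =
homogenization.  `%CC = 100(b−a)/(b+a)` on percentage contributions `a, b`
tracks each species' compositional gain/loss (−100 extinction, +100
introduction); the range index `(n_end − n_start)/|union of occupied plots|`
tracks occupancy change on [−1, 1].

## Worked example

The package embeds the published zone-level abundance table (three zones,
censuses 1986 and 2014, 25 species) as a fixture:

```python
import numpy as np
from sundiv import (table1_fixture, to_abundance_matrix, build_metacommunity,
                    subcommunity_alpha_bar, subcommunity_rho_bar,
                    metacommunity_gamma)
from sundiv.change import abundance_change_table

table = table1_fixture()
zones = ("hyposaline", "mesosaline", "hypersaline")
counts, species, labels = to_abundance_matrix(
    table, {z: ([z], [1986]) for z in zones})
mc = build_metacommunity(counts, species, labels)
for q in (0, 1, 2):
    print(q, np.round(subcommunity_alpha_bar(mc, q).values, 3),
          np.round(subcommunity_rho_bar(mc, q).values, 4),
          round(metacommunity_gamma(mc, q), 3))
```

prints

```
0 [21. 11.  9.] [0.9997 0.9852 0.9889] 23.0
1 [3.298 2.18  1.724] [0.9603 0.9338 0.7839] 2.723
2 [2.515 2.055 1.351] [0.9166 0.9047 0.7025] 2.182
```

Reading: in 1986 the hyposaline zone held 21 of the 23 pooled species and
the highest effective diversity at every q (ᾱ), while the hypersaline zone
was the most compositionally distinct from the pooled ecosystem (lowest ρ̄
once abundance matters, q ≥ 1) — it is dominated by two obligate halophytes.
The change table between the two censuses,

```python
change = abundance_change_table(table, 1986, 2014)
hyper = change[change.zone == "hypersaline"].set_index("species")
print(round(hyper.loc["Ceriops decandra", "cc_percent"], 2),
      round(hyper.loc["Heritiera fomes", "cc_percent"], 2))
```

prints `66.87 -21.66`: the invasive *Ceriops decandra* gained two thirds on
the composition-change scale in the hypersaline zone (257 → 1669 trees)
while the endangered climax species *Heritiera fomes* lost a fifth.

## Command line

```bash
sundiv simulate --strength 1.0 --seed 1 --out census.csv   # synthetic network
sundiv diversity --q 0 --zone hyposaline --year 1986       # profile to stdout
sundiv change --out results/                               # %CC + range table
sundiv map --census census.csv --metadata census_metadata.csv \
       --measure rho_bar --out maps/                       # kriged surfaces
sundiv all --config run.toml                               # full pipeline
```

The pipeline writes tidy CSVs, `.asc` grids and a `manifest.json` with
per-stage seeds and SHA-256 hashes; identical config + seed reproduces every
artifact byte for byte.

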