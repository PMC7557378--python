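# fec — fungal endophyte community analysis

`fec` is a Python package for the post-denoising analysis of fungal
endophyte communities (FECs) profiled by ITS amplicon sequencing across
multiple host species and collection sites. It was built around the
analysis of stem endophytes in bread wheat (*Triticum aestivum*) and two
wild wheat relatives (*Aegilops sharonensis*, *Triticum dicoccoides*), but
every stage operates on generic taxa × samples count tables.

It covers, end to end:

- **Curation bookkeeping** — species-level agglomeration of sequence
  variants, removal of shallow samples (< 1000 reads), singleton/doubleton
  and low-prevalence (incidence < 5) taxon filters, Venn partition of taxa
  by host, class-level composition, top-taxa ranking.
- **Alpha diversity** — incidence-based Hill numbers
  `⁰D` (richness), `¹D = exp(H_Shannon)`, `²D = 1/C_Simpson`, with
  sample-size rarefaction/extrapolation curves, bootstrap intervals, and
  asymptotic estimates (Chao2 for `q = 0`).
- **Beta diversity** — Bray–Curtis dissimilarity on Hellinger-transformed
  abundances and Dice dissimilarity on incidence; PCoA; one-factor
  PERMANOVA and ANOSIM with permutation p-values.
- **Kosman dispersion and differentiation** — assignment-based
  within-population dispersion `KW` (optimal fixed-point-free matching of
  plants), between-population Kosman distance `KB` (optimal one-to-one
  matching across populations), differentiation `D` from the additive
  partition of average-based dispersion with a permutation test, and the
  effective number of populations `¹D(TM) = 1 + (N−1)·M` with its
  normalized form `¹nD(TM) = (¹D(TM) − 1)/(N − 1)`.
- **Co-occurrence networks** — per-population Spearman associations at
  genus level (`p < 0.001`), discard of single-site edges, combined
  per-host networks with per-edge site counts and accumulated positive /
  negative rho, centrality profiles and composite hub ranking (high degree
  and closeness, low betweenness).
- **Synthetic surveys** — a generator of multi-host, multi-site count
  tables with known ground truth (core/sporadic/host-specific roles,
  host and site effects, correlated taxon pairs and modules injected via a
  Gaussian copula), so every stage has a parameter-recovery test without
  any external data.

## Worked example

```python
import numpy as np
import fec

# Kosman statistics on a toy 2+2-plant distance matrix
d = np.array([
    [0.0, 0.2, 0.7, 0.8],
    [0.2, 0.0, 0.8, 0.7],
    [0.7, 0.8, 0.0, 0.3],
    [0.8, 0.7, 0.3, 0.0],
])
print("KW =", fec.kw_dispersion(d))               # KW = 0.25
print("KB =", fec.kosman_distance(d[:2, 2:]))     # KB = 0.7
print(fec.effective_number(0.75, 4))              # (3.25, 0.75)

# Hill numbers of one synthetic population (30 plants)
cfg = fec.SyntheticConfig(hosts=["TA"], sites_per_host={"TA": ["Almagor"]},
                          plants_per_population=30, n_core_taxa=80,
                          n_sporadic_taxa=200, seed=7)
counts, meta, taxonomy, truth = fec.generate(cfg)
f = fec.incidence_frequencies(fec.to_incidence(counts))
for q in (0, 1, 2):
    print(f"q={q}: observed {fec.observed_diversity(f, q):.1f}, "
          f"asymptote {fec.asymptotic_diversity(f, q):.1f}")
```

prints

```
KW = 0.25
KB = 0.7
(3.25, 0.75)
q=0: observed 188.0, asymptote 303.1
q=1: observed 101.8, asymptote 106.6
q=2: observed 90.3, asymptote 90.5
```

`KW = 0.25` is the minimal average Dice distance when each plant is
matched to a different plant (here the two mutual pairs at 0.2 and 0.3);
`KB = 0.7` optimally matches the two plants of one population to distinct
plants of the other. A mean between-population distance of `M = 0.75`
among `N = 4` populations corresponds to 3.25 effectively distinct
populations (normalized 0.75). The `q = 0` asymptote (Chao2) estimates
~303 taxa present in the population, of which 188 were observed in 30
plants; the dominant-taxon diversity (`q = 2`) is essentially saturated.

The full pipeline is driven by a YAML config or the CLI:

```bash
fec simulate --seed 1 --out sim/           # survey-shaped synthetic data
fec run --config config.yaml               # filters → alpha → beta → kosman → network
fec report --out-dir out/
```

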