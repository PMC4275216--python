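# trflp

Dual-enzyme **T-RFLP** (terminal restriction fragment length polymorphism)
community profiling for fungal endophytes, built around the analysis of
*Alpinia officinarum* (lesser galanga) rhizome communities: from labeled
ITS amplicons and electropherogram peak lists to diversity statistics,
NMDS ordination, taxon affiliation, and active-chemical sample grouping.

## Who this is for

Microbial ecologists working with fragment-based community fingerprints
(or teaching/validating such pipelines) who need a fully scripted,
reproducible path from raw peak tables to ordination plots and letter
displays — including a seeded synthetic-data generator so every stage can
be exercised without sequencers or downloads.

## What it computes

- **In-silico digestion** — for a 5′-FAM-labeled amplicon, the terminal
  restriction fragment (T-RF) length under HhaI (GCG^C) and MspI (C^CGG)
  mono-digestion; an OTU is a distinct ordered (HhaI, MspI) length pair.
- **Profiles** — peaks filtered to 50–550 bp and ≥ 50 FU, relative
  abundance pᵢ = hᵢ / Σh, cross-sample single-linkage binning onto
  integer T-RF bins, replicate averaging.
- **Diversity** — Shannon H = −Σ pᵢ ln pᵢ (nats), Pielou evenness
  J = H / ln S (Heip and Sheldon selectable), Berger-Parker dominance
  d = max pᵢ, richness S.
- **Similarity** — Bray-Curtis S_BC = 1 − Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) and
  Jaccard |A∩B| / |A∪B| on presence supports; full pairwise matrices.
- **NMDS** — Kruskal stress-1,
  √(Σ(d̂ᵢⱼ−dᵢⱼ)² / Σdᵢⱼ²), with pool-adjacent-violators isotonic
  regression and SMACOF-style majorization over multiple restarts,
  written from scratch (scikit-learn is used only as a test oracle).
- **Taxon affiliation** — community T-RFs matched (± tolerance) against a
  bundled 25-OTU dual-enzyme affiliation table; genus-level abundance
  distributions from HhaI profiles with an explicit "unassigned" bucket.
- **Chemistry** — linear calibration fit/inversion, one-way ANOVA from
  (mean, SD, n) summaries, Duncan's multiple range test with protected
  levels α_p = 1−(1−α)^(p−1) and a compact letter display, letter-based
  High/Sub-high/Intermediate/Low grouping, and fold-excess summaries.
- **Synthetic data** — amplicons with planted restriction sites whose
  digest reproduces any feasible target pair, noisy electropherograms,
  multinomial clone libraries, and group-structured chemistry tables,
  all bit-reproducible under a fixed seed.

## Worked example

Simulate the bundled 12-sample study (four plant ages at one site plus
eight further sites, four planted chemical-content groups), profile it,
ordinate it, and attribute genera:

```python
from trflp import peaks as P, community as C, ordination as O, taxonomy as T
from trflp.simulate import (NoiseSpec, make_reference_design,
                            pool_pattern_table, simulate_electropherogram)

design = make_reference_design(seed=1)
profiles = [
    P.normalize(P.filter_peaks(
        simulate_electropherogram(c, design.pool, "HhaI", NoiseSpec(seed=1))))
    for c in design.communities
]
matrix = P.bin_align(profiles)                     # 12 samples x 9 T-RF bins
print(C.diversity_table(matrix).round(3).head(4))
result = O.nmds(C.pairwise_matrix(matrix, "bray_curtis"), seed=1)
print("stress:", round(result.stress, 4))
```

prints

```
           shannon_H  evenness  berger_parker  richness_S
sample_id
LT-4-RZ        1.648     0.793          0.499           8
GZ-RZ          1.835     0.943          0.313           7
QJ-RZ          1.834     0.942          0.279           7
LT-3-RZ        1.817     0.934          0.329           7
stress: 0.0
```

The high-content sample LT-4-RZ is the least even community (its 325-bp
HhaI T-RF — *Pestalotiopsis* — carries ~50 % of the signal), and the
12-sample Bray-Curtis ordination embeds essentially perfectly
(stress-1 ≈ 0, well under the < 0.11 quality bound used for these data).
Attributing its profile via the generating pattern table recovers the
planted genus abundances:

```python
tab = pool_pattern_table(design.pool)
row = matrix.loc["LT-4-RZ"]
T.genus_distribution({float(b): v for b, v in row.items() if v > 0}, tab, enzyme="HhaI")
# {'Pestalotiopsis': 0.499, 'Fusarium': 0.113, 'Penicillium': 0.081, ...}
```

The bundled chemistry table groups from the command line:

```
$ trflp chemgroup --analyte volatile_oil
sample_id	mean	letters	group
LT-4-RZ	14.65	d	High
QJ-RZ	10.44	c	Sub-high
LT-3-RZ	10.1	c	Sub-high
GZ-RZ	9.96	c	Sub-high
KM-RZ	7.92	b	Intermediate
...
HA-RZ	2.98	a	Low
```

Samples sharing a letter do not differ at p < 0.05 under Duncan's test;
the four letter classes are the four content groups.

Other CLI subcommands: `simulate`, `digest`, `profile`, `diversity`,
`ordinate`, `affiliate`, `run` (full pipeline from a YAML config); see
`trflp --help`.

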