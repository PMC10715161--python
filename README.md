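# enteroeco

Enterotype discovery and community-ecology statistics for gut microbial
census data.

Gut communities of wild mammals often fall into a small number of
recurring compositional configurations — *enterotypes* — each dominated
by a few driver genera, and the balance between them can shift with
season, altitude and host physiology. `enteroeco` implements the full
analysis chain used to characterise such structure from amplicon feature
tables: enterotype clustering, diversity and ordination statistics,
co-occurrence networks, community-assembly inference, and the group
contrasts that link enterotypes to host ecology. It is aimed at
microbial ecologists who have finished feature tables (ASV or genus
level), a phylogeny and sample metadata, and want the downstream
statistics in one reproducible, scriptable pipeline.

## The methods at the core

**Enterotyping.** Samples are compared by the Jensen–Shannon distance
between genus-level relative-abundance profiles,

d(i, j) = sqrt[ ½ KL(p_i ‖ m) + ½ KL(p_j ‖ m) ],  m = (p_i + p_j)/2,

clustered by partition around medoids (PAM) for each candidate k, and
the number of enterotypes is chosen by the Calinski–Harabasz index,
CH(k) = [B/(k−1)] / [W/(n−k)], evaluated on the PCoA embedding of the
distances (a distance-only medoid form of CH is also provided). Each
cluster's *driver genera* are the top-abundance genera that are
significantly more abundant there than in every other cluster
(one-sided Mann–Whitney tests, Benjamini–Hochberg corrected).

**Diversity.** Shannon entropy H = −Σ p log p and bias-corrected Chao1
S_obs + F₁(F₁−1)/(2(F₂+1)) per sample; Bray–Curtis dissimilarity,
classical PCoA (Gower double-centering), and a one-way PERMANOVA with
pseudo-F = [(SS_T − SS_W)/(g−1)] / [SS_W/(n−g)] under whole-label
permutation.

**Networks.** Within each enterotype, taxa above 0.5% total relative
abundance are correlated pairwise (Spearman by default); edges with
|r| > 0.7 (bacterial preset) at p < 0.05 form the co-occurrence graph,
summarised by node/edge counts, mean degree, clustering coefficient and
greedy (CNM) modularity Q.

**Community assembly.** ses.MNTD standardises each community's mean
nearest-taxon phylogenetic distance against a taxa-label-shuffling null
(ses < −2: phylogenetic clustering; ses > +2: overdispersion; between:
stochastic assembly). The Sloan neutral model predicts a taxon's
occurrence frequency from its mean relative abundance p via
1 − I_d(Nmp, Nm(1−p)) with detection limit d = 1/N; the migration rate
m is fitted by least squares, Nm estimates dispersal, R² the neutral
fit, and taxa are partitioned above/below/within the Wilson confidence
band of the prediction.

**Synthetic data.** A first-class generator module produces datasets
with exactly the structure these methods assume: Dirichlet-multinomial
mixtures with boosted driver genera, Yule phylogenies sampled at random
or within subclades, Sloan-law metacommunities with known m, and host
metadata with planted enterotype effects — so the entire pipeline is
testable offline.

## Worked example

```bash
enteroeco run --seed 7 --outdir out/
```

simulates the default bacterial-style scenario (60 samples, 50 genera,
three planted enterotypes) and runs every stage. The report
(`out/report.md`) includes:

```
Chosen k = 3 by the CH index (k-means elbow at k = 3).
Cluster sizes: {1: 25, 2: 18, 3: 17}.
Adjusted Rand index vs planted labels: 1.000.
PERMANOVA between enterotypes: pseudo-F = 82.85, R^2 = 0.744, p = 0.001.
### Enterotype x season
chi-square = 29.62, df = 2, p = 3.701e-07
```

Read: the CH curve peaks at three clusters, which reproduce the planted
labels perfectly; enterotype identity explains 74% of the Bray–Curtis
community variance; and the planted seasonal shift in enterotype
proportions is recovered as a strongly significant chi-square.

The same stages are available as library calls — see the numbered
scripts under `analysis/` (simulate → enterotype → diversity → network →
assembly → contrasts), each of which writes its tables under
`results/`. Every stochastic stage takes an explicit seed, and re-running
a pipeline from its `manifest.json` reproduces all outputs bit for bit.

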