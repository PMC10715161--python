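# Methods

This note records the models, the parameter choices that matter, the
numerical decisions taken where the design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Data model and preprocessing

All stages operate on a samples × taxa `AbundanceTable` of counts or
relative abundances. Feature tables are TSV (orientation normalised at
read time); trees are Newick with branch lengths (missing lengths become
0 with a warning); metadata requires `sample_id`, `season`
({warm, cold}) and `altitude_m`. The altitude class is `high` strictly
above 3,900 m — the boundary itself is `low`, reading "over" strictly.
Derived columns (`altitude_class`, `rmr_per_mass` = RMR / mass) are
computed at read time.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric draw) to a common depth, by default the minimum sample
sum; samples below the depth are dropped, not padded, so retained row
sums are exact. Genus aggregation sums taxa sharing the genus label of a
`;`-separated lineage; taxa with an uninformative genus token are pooled
under their nearest informative ancestor as `unclassified_<ancestor>`
(or `norank_<ancestor>` when the annotation says norank), matching the
naming convention of amplicon taxonomy tables. The pipeline aggregates
*after* rarefaction and records that choice in its manifest. The matrix
grand total is conserved by aggregation; this is tested.

## Enterotyping

Jensen–Shannon distances use natural log with 0·log 0 = 0 and no
pseudocount: the mixture m = (p+q)/2 is positive wherever either term
contributes, so no epsilon is needed; a pseudocount option exists only
for parity with legacy scripts. Distances are bounded by √(ln 2).

PAM minimises Σᵢ d(i, nearest medoid). Instances with at most 10,000
candidate medoid sets are solved exactly by enumeration; larger
instances use the classic BUILD phase followed by best-improving SWAP
exchanges. The cutover exists because BUILD+SWAP is a local search: on
random small instances it (like the reference R implementation) misses
the global optimum on roughly 5% of cases, whereas at these sizes the
optimum is cheap to enumerate. Ties break toward the lexicographically
smallest sample id throughout, which makes clustering deterministic and
permutation-equivariant.

Two Calinski–Harabasz formulations are provided. `ch_index` is the
distance-only medoid form (W from squared distances to cluster medoids,
B from size-weighted squared medoid-to-global-medoid distances). For
*model selection*, `select_k` defaults to the classic centroid CH
computed on the PCoA embedding of the distance matrix. The medoid form
has a structural defect as a selection criterion: the cluster containing
the global medoid contributes zero to the between term, which deflates
CH for the correct k and favours merging nearby clusters; on the
bacterial-like preset this mis-selects k in 10–20% of seeds even when
the k=3 PAM partition is perfect, while the centroid form selects
correctly in every tested instance. Chosen k maximises CH with ties to
the smaller k. Cluster labels are 1-based, ordered by decreasing size
(ties by smallest medoid id). The k-means/WSS elbow curve is a
diagnostic companion: k-means needs coordinates, so it runs in PCoA
space with 10 restarts plus a warm start from the previous k's solution,
which guarantees a non-increasing WSS curve; the elbow maximises
perpendicular distance from the endpoint chord.

Driver genera: within each cluster, genera are ranked by mean relative
abundance; a genus is a driver while every one-sided Mann–Whitney
comparison against each other cluster stays significant after
Benjamini–Hochberg correction (per-cluster family) at α = 0.05.
Clusters with fewer than 3 samples are retained in assignments but
flagged and excluded from driver detection and downstream group
statistics.

## Diversity, ordination, PERMANOVA

Shannon defaults to natural log (base-2 selectable; the base is recorded
in output metadata). Chao1 is the bias-corrected form, defined when no
doubletons exist. PCoA Gower-centres −½D², keeps positive eigenvalues
only (tolerance 1e-10 relative to the leading eigenvalue), reports
negative ones, and fixes axis signs so the largest-magnitude loading is
positive. PERMANOVA is one-way, 999 permutations by default, p-value
with the +1 correction; permuted statistics within 1e-12 of the observed
count as ties in its favour.

## Co-occurrence networks

Taxa are filtered by share of the table's grand total (> 0.5% by
default). The default correlation is Spearman with p < 0.05 and
|r| > 0.7; Pearson with p < 0.01 is selectable because published
protocols vary on this point. Spearman is computed as Pearson on ranks;
p-values come from the t approximation. No multiple-testing correction
is applied to edge p-values by default (a BH option exists). Isolated
filtered taxa are excluded from node counts by default. Modularity uses
greedy agglomerative (CNM) maximisation on the unweighted edge set —
correlation magnitudes are stored on edges but not used as weights — and
module membership is reported with deterministic ordering. Mean local
clustering counts degree-<2 nodes as zero.

## Community assembly

MNTD is unweighted (presence-based) by default — the mean over member
taxa of the distance to the nearest other member — with an
abundance-weighted option. The ses.MNTD null shuffles taxon labels
across the full cophenetic matrix (one shared permutation per replicate
across samples), 999 replicates by default; ses = (obs − null mean) /
null sd with sd computed over replicates (ddof 1). Classification:
clustered below −2, overdispersed above +2, random between, and
undefined when the sample has fewer than 2 taxa or spans the whole tip
pool (the shuffle is then a no-op and the null sd collapses); undefined
never propagates NaN into downstream proportions.

The Sloan neutral fit estimates N as the mean sample sum (overridable),
d = 1/N, and m by bounded scalar least squares of observed occupancy on
1 − I_d(Nmp, Nm(1−p)) over m ∈ (1e−6, 1]. R² = 1 − SS_res/SS_tot on raw
occurrence frequencies (the formula is recorded in the output). Two
abundance estimators are available. The observable mean relative
abundance is censored at the detection limit — a table records nothing
below one read — and at desk-scale depths (hundreds of taxa at N ~ 10³)
that censoring understates p for transition-zone taxa enough to inflate
a naive m̂ by 15–40%. The default therefore inverts the censored moment
E[x·1{x>d}] = p(1 − I_d(Nmp+1, Nm(1−p))) under the fitted model
(bisection per taxon inside the m search); `detected_mean` preserves the
legacy convention. Scale consistency (counts × c with N held at the
stated depth leaves p, frequencies and m̂ unchanged) holds exactly and
is tested.

Taxon partitioning uses the Wilson score interval around the predicted
frequency at the realised sample count (95% by default; a normal
approximation is available via statsmodels options). Because occupancy
is an integer count of samples, a taxon must exceed the band by more
than half a sample to be called above/below; without that resolution
margin a 40/40-occupancy taxon would be called "above" a predicted
0.9996 on a 4×10⁻⁴ residual.

## Synthetic-data generators

**Enterotype tables** are Dirichlet-multinomial mixtures: base
concentrations are 40·w with w a normalised log-normal(0, 1) weight
vector over 50 genera; cluster c multiplies its 2 driver genera — the
top-weight genera, two per cluster — by 8. Defaults (60 samples, depth
10⁴, K = 3 bacterial-like / K = 2 fungal-like presets) were chosen so
that each enterotype is dominated by a couple of already-abundant
genera, the pattern the method is designed to detect; with them the
planted structure is recovered (correct k, ARI ≥ 0.9) in 100/100 seeds.
The generator plants *cluster* structure only: taxa are conditionally
independent given the cluster, so within-cluster co-occurrence networks
are expectedly sparse — network power is instead tested on planted
two-block correlation data.

**Phylogeny communities**: Yule (pure-birth) trees; the `random`
scenario draws each sample's taxa uniformly from the tips, the
`clustered` scenario from one randomly chosen *minimal* qualifying
subclade (at least 2× the per-sample richness but no qualifying child
clade) — the tightest clades that can host a community, hence the
strongest planted signal; drawing from all qualifying clades would
include near-root clades and dilute it. Calibration and power runs use
a 200-tip pool with richness 10.

**Neutral metacommunities**: log-series (shape 0.999) metacommunity
abundances; each sample's per-taxon relative abundance is drawn from the
stationary Beta(Nmp, Nm(1−p)). The default realisation keeps reads
real-valued at N·x and censors below the detection limit, making the
generator exactly the process the fit inverts, so parameter recovery is
a clean oracle (m̂ within a few percent at m ∈ {0.05, 0.1, 0.3}). A
`binomial` realisation (integer counts, extra sampling layer) is
available for realism studies; it smooths occupancy near d and is the
documented source of upward bias in naive fits.

**Host metadata**: body temperature, RMR and mass are
Normal(μ_enterotype, σ) at plateau-pika scale (≈39–40 °C, ≈3 mL CO₂/min,
≈150–170 g); season and altitude class follow per-enterotype probability
rows echoing the warm-type/cold-type/generalist pattern; altitude in
metres is uniform within the class band.

What passing tests show: the statistics are correct against closed
forms and independent oracles, calibrated under their own nulls, and
powerful against their own planted alternatives. What they do not show:
robustness to features real data have and the generators omit —
sequencing noise and compositional bias, taxon-taxon interactions,
overdispersion beyond Dirichlet-multinomial, or phylogenies with
calibration error.

## Problem sizes and runtime choices

Default test and acceptance runs use 60-sample tables at depth 10⁴,
200-tip trees, 199–999 permutations/null replicates, and 10–20 seeds
per recovery experiment; these sizes give stable pass/fail behaviour
for the planted effects while keeping a full run in minutes on one
core. The pipeline writes a manifest (config snapshot, seeds, input
checksums) before computing; re-running from the manifest reproduces
every output byte for byte, which is itself under test.

## Known limitations

One-way designs only (no covariates, no stratified or nested
PERMANOVA); no compositionality-aware network inference (SparCC-style);
the neutral fit assumes a common depth and one metacommunity per group;
enterotype number is selected by CH only (no Dirichlet-multinomial
mixture model comparison); BIOM input is not supported (TSV only).
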