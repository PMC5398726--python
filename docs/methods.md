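# Methods

This note documents the models, conventions, and numerical choices behind
venomkit, and what the synthetic-data tests do and do not demonstrate.

## Digestion and emPAI

The trypsin/Lys-C mix is modeled as cleavage C-terminal to lysine (K) or
arginine (R). The classical no-cleavage-before-proline exception is applied
to R only: Lys-C cleaves K–P bonds, so the mix leaves only R–P intact. The
rule is a flag (`DigestionConfig.block_proline_after_r`) because the
convention varies across search engines. Digestion enumerates peptides
bounded by cleavage sites or termini with at most `max_missed_cleavages`
internal sites (default 2) and at least `min_peptide_length` residues
(default 6), matching common database-search settings.

A peptide counts as *observable* if some allowed precursor charge places it
inside the instrument scan range. With m/z in [300, 1800] and charges 2–6,
the neutral monoisotopic mass window is

  [mz_min·z_min − z_min·m_p, mz_max·z_max − z_max·m_p] ≈ [598.0, 10794.0] Da,

with m_p = 1.00728 Da the proton mass. Masses are monoisotopic residue
masses plus one water; cysteine carries fixed carbamidomethylation
(+57.02146 Da), reflecting iodoacetamide alkylation. Variable
modifications are ignored for observability counting: they change a
peptide's mass by tens of daltons, which rarely moves it across a
~10 kDa-wide window.

`N_observed` counts **distinct peptide sequences** per protein by default,
the convention of the emPAI literature; an ion-count mode is available.
Shared peptides credit every protein containing them (no parsimony).
emPAI = 10^(N_obs/N_obsbl) − 1 is zero when nothing was observed, and a
protein with observations but no observable peptides is a contract
violation rather than a silent zero. Molar fractions divide each emPAI by
the catalog sum.

## Conservation categories

Venom proteins are categorized from the species composition of their
orthology cluster with the precedence **distant > sister > specific**,
which turns the three published categories into a true partition (the
categories are presented as exclusive pie slices, but a cluster can contain
both distant and sister members; precedence resolves this). Species in the
`other` group (e.g. *Heterorhabditis bacteriophora*, an entomopathogen that
is neither *Steinernema* nor vertebrate-parasitic) never promote a cluster
out of `focal_specific`. Venom proteins absent from every cluster become
singleton focal-specific clusters before categorization, so counts always
sum to the venom size. Cluster ranking ties are broken lexicographically
by cluster id.

Because published figures quote the genus-specific share of venom
*molecules* pooled across the sister and focal categories, the molar
breakdown reports the three exclusive percentages **and** the pooled
`steinernema_specific` value.

## Family coverage

Domain hits are filtered at E ≤ 1e-6 (the stringent profile-HMM threshold
used for proteome-wide Pfam assignment). The coverage statistic is
deliberately asymmetric — distinct *genes* in the denominator, venom
*proteins* in the numerator — matching the published table convention; a
flag forces gene-level counting on both sides. Percentages are rounded
half-up. Pfam version suffixes are stripped so re-annotations aggregate.

## Expression integration

- Batch correction is per-gene batch-mean centering (equivalent to
  regressing out a batch indicator with no covariates). When a batch is
  confounded with condition — as when two in-vivo time points are processed
  on a separate day — this removes condition signal along with the
  technical offset; that trade-off is inherent to the design, not to the
  estimator.
- Quantile normalization maps each sample's values to the row-wise mean of
  per-sample sorted vectors; ties receive the mean of the reference values
  at their tied ranks (average-rank interpolation, as in limma's
  `normalizeQuantiles`).
- DE calls consume externally computed (log2 fold change, FDR) tables and
  apply strict thresholds: FDR < 0.05 and |log2FC| > 1 ("fold change
  > 2×"). The DE test itself (negative-binomial machinery) is out of scope.
- Venn percentages are relative to the union of the two DE sets, matching
  how shared fractions of up/downregulated venom genes are quoted.
- Proximity grouping chains genes on the same scaffold whose ordinal-index
  gap to the nearest group member is ≤ 10 (single-linkage transitive
  closure, per scaffold). Ordinal index — the gene's rank along its
  scaffold — is the distance measure; "within 10 genes" has no base-pair
  meaning. Singletons are not groups.
- Sample k-means uses 50 restarts with a fixed seed; k is a user input.
- RNA–protein correlation is Spearman's rho over the top-100 proteins by
  emPAI, paired with their gene's expression.

## Dosimetry

Measured per-worm rates are inputs, not derived quantities: the published
bulk figures (~100 µg from ~2 million worms) give 0.05 ng/worm while the
study's own calculation uses 0.061 ng/worm/3 h, so the module only performs
the extrapolation and equivalence arithmetic on whatever rate it is given.
Extrapolation is linear in time and reported to 2 decimals (ng);
worm-equivalents round to the nearest integer — these conventions reproduce
the printed 0.49 ng/24 h and ~20 worms. Activation standard errors use the
sample (n−1) standard deviation over replicate proportions divided by √n;
a single replicate yields SE = 0 and is flagged via `n_replicates`.

## Synthetic-data generator

The generator's defaults mirror the headline shape of the study: 472 venom
proteins among 28,313 genes, 321 venom clusters, 14 species (focal + 4
sister *Steinernema* + 8 vertebrate-parasitic + 1 other), 43% of venom
proteins distant-conserved, ~85% of venom molecules genus-specific, DE Venn
designs of 135 shared of 210 upregulated and 65 of 88 downregulated, and
178 proximity-query genes of which 79 lie in planted groups of size 2–5
(31 groups; planted mean group size 2.55). The 57% non-distant venom share
is split 22% sister-conserved / 35% focal-specific; only the pooled 57% is
constrained by the published counts, so the split is a design choice.
`SyntheticDesign.small()` scales everything down ~50× for fast tests.

Model choices, all parameterized in the design:

- **Sequences**: random amino-acid strings of 80–600 residues with K/R
  frequency ≈ 11%, so tryptic peptides exist at realistic density.
- **Molar abundances**: log-normal (σ = 1.0), deterministically rescaled so
  distant-conserved proteins carry exactly their designed share (15%) of
  total abundance.
- **Peptide detection**: each observable peptide is detected independently
  with probability p(A) = min(1, log10(1 + s·A/median(A))) in planted
  abundance A (scale s = 0.8). This is the inverse of the emPAI model —
  under it E[N_obs/N_obsbl] makes emPAI proportional to abundance — so
  planted molar shares are recoverable by the statistic that consumes the
  data. A logistic link in standardized log-abundance is available as an
  alternative; it preserves rank recovery but compresses large abundances,
  biasing molar-share recovery.
- **Expression**: negative-binomial counts (dispersion 0.1) around
  2^(baseline + condition effect + batch offset); batch offsets are
  per-gene Gaussian (σ = 0.6 log2 units) applied to the conditions
  processed "on a different day". A noiseless mode emits exact
  2^signal − 1 values (clipped at zero) for exact-recovery tests.
- **DE tables**: planted DE genes get |log2FC| > 1.05 and FDR < 0.049;
  all other genes get |log2FC| < 0.95, so threshold filtering recovers the
  planted sets exactly and the designed Venn overlaps are reproduced
  deterministically.
- **Proximity**: planted groups use adjacent gaps of 1–3 (window 10) and
  inter-group separations > window; background genes fill all remaining
  ordinal slots so scaffold indices are contiguous.

Every generator is deterministic given the design seed (each stage derives
an independent stream from the seed and a stage tag), and every generator
emits machine-readable truth.

### What the synthetic tests do not show

The generator emulates the *statistical structure* the analyses assume, not
real data: sequences are i.i.d. letters (no homology, domains, or signal
peptides), orthology clusters are assembled to a design rather than
inferred from similarity, detection is independent across peptides (no
ionization or length biases beyond the mass window), and expression has no
gene–gene correlation. Passing planted-truth tests therefore demonstrates
that the implementations compute their definitions correctly and recover
designed signal at realistic sizes and noise levels — not that the upstream
measurement models are faithful to any particular instrument or genome.

## Problem sizes in the test suite

The default test and acceptance runs use the scaled-down design (400 genes,
60–300 venom proteins) for digestion-heavy steps and the full 472-protein /
178-gene designs for the conservation, Venn, and proximity computations,
which are cheap. A full 28,313-gene expression matrix generates in
seconds; digesting the full proteome is supported but unnecessary for any
shipped analysis.
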