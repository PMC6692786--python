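# Methods

`cnvbuffer` implements an analysis chain for quantifying how gene
copy-number variation (CNV) is buffered at the protein level, and for
attributing that buffering to physical protein interactions. Because the
real multi-omics compendia it is designed for (tumour proteogenomics
cohorts, normal-tissue expression atlases, eQTL catalogues) cannot be
redistributed, the package ships a first-class synthetic-data generator
whose hidden parameters serve as recovery targets for every stage.

## Generative model of the synthetic cohort

For each gene *g* and sample *i*:

- **Copy number** `C_ig` is a discretized GISTIC score in {−2,−1,0,1,2},
  drawn i.i.d. per genomic block from `cnv_level_probs`
  (default (0.05, 0.20, 0.50, 0.20, 0.05), i.e. diploid-centred with
  symmetric gains/losses). Genes are laid out on `n_chromosomes` (22) in
  blocks of `colocalization_block_size` (5) positions; a gene copies its
  block's draw with probability `cnv_block_coupling` (0.9), else draws
  independently, producing the within-block CNV correlation that mimics
  segmental co-amplification. A fraction `frac_colocalized_controllers`
  (0.05) of controller→controlled pairs is deliberately placed adjacently
  in one block; interacting human proteins are rarely genomic neighbours,
  and these pairs exist to exercise the co-localization filter — their
  attenuation signal is partially masked by construction.
- **mRNA** (log scale): `T_ig = s·C_ig + covariate effects + ε`,
  with dosage slope `s = 1` and `ε ~ N(0, 0.5)`.
- **Protein** (log scale): non-attenuated genes track their own mRNA,
  `P_ig = T_ig + covariate effects + ε_P`, `ε_P ~ N(0, 0.5)`. Attenuated
  (controlled) genes mix in the *realized protein* of a controlling
  complex partner *x*:
  `P_ig = (1−b)·T_ig + b·P_ix + covariate effects + ε_P`,
  with buffering strength `b = 0.8` (high class) or `b = 0.4` (low class).
  This encodes the complex-assembly mechanism: surplus subunits are
  degraded, so the controlled subunit's abundance follows the rate-limiting
  partner. The implied controller-CNV effect size is β₇ = b·s.
- **Classes**: `frac_attenuated = 0.42` of genes are controlled, of which
  `frac_high_within_attenuated = 0.25` are high-buffering — both ratios
  taken from the attenuated/non and high/low proportions reported for
  tumour proteomes. Every complex has one designated controller (never
  attenuated); controlled genes are drawn from the remaining members of
  140 complexes of 4–12 subunits.
- **Covariates**: cancer type (3 levels), batch (4), proteomics technology
  (2), gender (2) and age act additively on the log scale with per-level,
  per-gene effects of SD 0.1–0.3 — large enough that skipping confounder
  regression visibly corrupts the correlation estimates.
- **Phosphosites**: ~30% of genes carry one site, `Pho = P_parent +
  N(0, 0.5)`; for 20% of edges the controller's site feeds into the
  controlled protein with coefficient `phospho_effect = 0.4`, giving the
  phospho screen a signal component independent of the parent protein.
- **Missingness** is completely at random (10% protein, 30% phospho),
  matching the package's threshold-based coverage filters; no
  intensity-dependent censoring is modelled.

What the generator does *not* emulate: tumour purity and clonality, read-
level count noise, intensity-dependent missingness, genome-coordinate
realism beyond block co-localization, and correlated complex-wide
regulation beyond single controller→controlled edges. Passing recovery
tests therefore demonstrate the *statistical identifiability* of the
analysis under the stated model, not robustness to every artefact of real
proteomics data.

## Attenuation statistic and classification

Per gene, the attenuation potential is
`corr(C, T) − corr(C, P)` (Pearson, pairwise-complete samples, minimum 20
complete pairs, CNV treated as numeric). Genes with buffered proteins show
dosage in the transcriptome but not the proteome, giving large positive
potentials.

Classification fits a 1-D Gaussian mixture with 4 components (full
covariances, EM with k-means++ initialization, 50 restarts, tolerance
1e-8, fixed seed). Components are reduced to three classes:

1. Negative-mean components merge into the lowest nonnegative-mean
   component — a gene whose protein tracks CNV *better* than its mRNA is
   not attenuated.
2. While more than three groups remain, the adjacent pair with the
   smallest mean separation scaled by pooled spread
   (|Δμ|/√(σ²₁+σ²₂)) is merged.

Step 2 replaces a fixed "merge the two lowest" fallback: which cluster the
surplus 4th component subdivides is data-dependent (on real tumour data it
captured a small negative tail; on synthetic potentials it splits the wide
high-buffering cluster), and proximity merging absorbs it into whichever
cluster it came from. Classes are labelled non/low/high by ascending mean;
genes are assigned by maximum posterior responsibility.

Complex enrichment of the attenuated set uses the one-sided upper-tail
hypergeometric test over complexes with >5 members, after greedy
near-duplicate removal (descending size, drop any complex with Jaccard
≥ 0.9 against a kept one), with Benjamini–Hochberg FDR.

## Interaction-control screens

For a directed pair (X, Y) the null model predicts Y's protein from Y's
mRNA plus covariates (cancer type, batch, technology, age, gender,
dummy-coded); the alternative adds X's CNV (CNV variant) or X's mRNA
(mRNA variant). Both models are OLS on the identical complete-case sample
set; with the Gaussian likelihood at the MLE variance RSS/n the likelihood
ratio statistic reduces to `LRT = n·ln(RSS₀/RSS₁)`, referred to χ²(1).
This matches the standard `lm` + likelihood-ratio-test workflow and is
mildly anticonservative at n in the hundreds (mean null LRT ≈ 1.03–1.07);
the Benjamini–Hochberg step absorbs this in practice, and the calibration
check in the acceptance suite summarizes several independent null screens
by their median Kolmogorov–Smirnov p-value because single-screen KS on
10,000 *dependent* pairwise tests over-rejects.

Significant pairs are those below FDR 5% in **both** the CNV and mRNA
screens (strict <). Same-chromosome controllers of one controlled gene are
then deduplicated: Borda aggregation of the CNV-screen and mRNA-screen
p-value orderings (rank sum, ties by smaller CNV p then gene id) picks the
top controller, and further same-chromosome controllers survive only if
their CNV profile correlates < 0.5 (Pearson) with every retained one. The
filter never removes a controlled gene entirely. Genes are finally
labelled controlling / controlled / both.

The phospho screen conditions on more: base predictors are Y's mRNA, X's
CNV and protein, plus batch, age and gender; the added predictor is a
phosphosite of X. Significant phosphosite associations are reported, and
the final set is their overlap with the protein-level significant pairs
(directionality guard). Added predictors that are constant or collinear
with the base design (residual variance ≤ 1e-10 of total) are skipped with
a reason, as are pairs with too few complete cases (n ≤ parameters + 3).

## Structural interface analysis

SASA uses the Shrake–Rupley method: 960 quasi-uniform golden-spiral points
per atom at radius r_vdw + 1.4 Å (probe), a point being accessible when
outside every other inflated sphere. Element-based single radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å) and per-residue relative SASA
against a theoretical maximum-ASA reference table follow common
accessibility-tool conventions; hydrogens and hetero atoms are stripped.
Because the sphere points are fixed, bound per-residue SASA is *exactly*
bounded by the unbound value, and interface sets are exactly invariant
under rigid motion (areas move only by the ~1% point-quadrature error —
the lattice has a fixed global orientation, so areas are not
rotation-invariant to machine precision; no point-sampling implementation
is).

A residue is an interface residue when its relative SASA changes by more
than 1e-4 (relative units; 0.01 Å² absolute for residue types without a
reference maximum) between the complex and the isolated chain — a literal
"any change" rule is numerically meaningless under point sampling, so the
tolerance is explicit and configurable. Structure QC drops homodimers,
models with < 100 total residues, chains longer than their UniProt length,
and two-chain models with equal chain lengths. Per-protein interface
fraction is the union of interface residues across retained structures
over the UniProt length (clamped at 1); per-chain burial is
(SASA_unbound − SASA_bound)/SASA_unbound. Interface size is correlated
(Pearson, with t-test p) against the association effect size β₇ and
−log10 FDR.

## Tissue and eQTL validation

Tissue panels: sub-tissues (heart, esophagus, colon style) are averaged,
genes kept when expressed — nonmissing and nonzero — in ≥ 10 of 14
tissues in *both* matrices (the joint reading of the coverage rule), then
rows are z-scored and quantile-normalized in that order. Per pair, three
Pearson correlations over complete tissue pairs (≥3) are computed:
protein–protein, mRNA–mRNA, and mRNA–protein of the controlled gene; the
optional mRNA-correlation band [0, 0.4] (inclusive) controls for
co-expression when comparing strata by rank-sum test.

eQTL stratification: variants keep a gene association when their slope
sign is consistent (modal sign) in ≥ 3 tissues; per gene, LD blocks are
connected components at r² > 0.8 (strict), genes with > 100 blocks are
excluded before tagging; a block is GWAS-tagging when any member is a
catalogue variant or has a proxy at r² > 0.8 in the catalogue. Tagging
fractions are reported per attenuation class over cumulative tissue-count
strata, optionally restricted to genes with CNV–mRNA r > 0.3 and/or a
complex-membership subset; empty strata are NaN, not zero.

## Numerical and scale choices

- Quantile normalization: complete columns get the exact sorted-mean rule
  with tie groups receiving the mean of their quantile span; columns with
  missing values are mapped by rank fraction onto the mean quantile grid
  of observed values.
- TMM: trim 30% on M-values and 5% on A-values, precision weights by the
  delta method, reference = sample whose upper quartile is closest to the
  mean upper quartile; factors normalized to geometric mean 1; output
  log2-CPM with a 0.5 prior count.
- The z-score step drops constant rows with a warning; confounder
  regression fits each feature on its observed entries and drops aliased
  design columns.
- Default problem sizes in the test and acceptance runs — cohorts of 368
  samples × 2,000 genes, 10–20 seeds per Monte-Carlo check, null screens
  of 10,000 pairs, tissue panels of 400 genes × 14 tissues — were chosen
  as the smallest sizes at which the Monte-Carlo standard errors are an
  order of magnitude below the asserted margins.
- Determinism: every stochastic step takes a seed; the pipeline manifest
  records parameters and SHA-256 checksums of all outputs, and identical
  configurations reproduce identical files.

## Known limitations

- The attenuation statistic cannot see buffering when controller and
  controlled gene are co-amplified (correlated CNV) — by design these
  pairs are handled by the co-localization filter, not recovered.
- The LRT p-values inherit the finite-sample anticonservatism of the
  MLE-variance Gaussian likelihood ratio; exact F-tests would calibrate
  better but would not match the statistic this package is specified to
  compute.
- Relative SASA is undefined for residue types outside the 20-standard
  reference table (absolute areas are used for the interface rule there).
- The eQTL generator produces block-structured LD directly rather than
  deriving it from genotypes; it validates the block/tagging logic, not
  LD estimation.
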