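# cnvbuffer

Gene copy-number changes usually propagate to mRNA, but for a large
fraction of genes — predominantly subunits of protein complexes — they
are *buffered* at the protein level: surplus subunits are degraded until a
rate-limiting partner sets the achievable abundance. `cnvbuffer` is a
toolkit for quantifying this buffering from matched CNV / mRNA / protein /
phosphoproteome cohorts and for dissecting its mechanism, aimed at
computational biologists working with tumour proteogenomics or multi-omics
perturbation data.

The chain it implements:

1. **Attenuation.** Per gene *i*, the attenuation potential
   `corr(CNVᵢ, mRNAᵢ) − corr(CNVᵢ, Proteinᵢ)` (Pearson); a 4-component
   Gaussian mixture clusters the potentials and the components are merged
   into non / low / high attenuation classes, followed by hypergeometric
   complex enrichment.
2. **Interaction control.** For each physical interaction pair (X, Y),
   nested linear models
   `P_Y ~ T_Y + covariates` (null) vs `P_Y ~ T_Y + covariates + G_X`
   (alternative) are compared by the likelihood-ratio test
   `LRT = n·ln(RSS₀/RSS₁) ~ χ²(1)`, with Benjamini–Hochberg FDR, an
   mRNA-variant confirmation screen, Borda-rank deduplication of
   genomically co-localized controllers, and controlling / controlled /
   both status calls. A phospho variant conditions on X's CNV and protein
   and tests a phosphosite of X.
3. **Interface geometry.** Shrake–Rupley solvent accessibility on
   binary-complex structures; a residue is an interface residue when its
   relative SASA changes between the bound complex and the isolated
   chain; interface sizes are correlated with the association statistics.
4. **Validation.** Controlling→controlled pairs are tested for the
   predicted correlation signatures across normal-tissue panels, and
   cis-eQTL LD blocks are stratified by attenuation class to compare
   GWAS-tagging fractions.

Because the real compendia are not redistributable, the package includes a
synthetic-cohort generator (`cnvbuffer.simulate`) that emulates the
statistical structure of such data — dosage propagation, buffering through
complex membership, confounders, chromosomal co-amplification,
phospho-dependent assembly — with full ground truth, so every stage is
testable against known answers.

## Worked example

```sh
cat > demo.yaml <<'YAML'
out_dir: demo_run
seed: 11
simulation:
  n_samples: 150
  n_genes: 600
  n_complexes: 45
YAML
buffer-pipeline run --config demo.yaml
buffer-pipeline report demo_run
```

prints

```json
{
 "attenuation_class_counts": {
  "non_attenuated": 361,
  "low_attenuated": 179,
  "high_attenuated": 60
 },
 "n_genes_scored": 600,
 "n_associations_cnv_tested": 3032,
 "n_associations_final": 262,
 "n_phospho_tested": 996,
 "control_status_counts": {
  "controlled": 247,
  "controlling": 45,
  "both": 10
 },
 "n_phospho_final": 31,
 "association_true_positives": 250,
 "association_false_positives": 12,
 "n_true_edges": 252,
 "eqtl_fraction_rows": 9
}
```

Reading this: of 600 simulated genes, 239 (40%) were classified attenuated
(the generator planted 42%); the CNV+mRNA double screen plus
co-localization filter recovered 250 of the 252 planted
controller→controlled edges with 12 false calls; 31 phosphosite
associations overlap the protein-level set. Stage outputs (attenuation
table, association tables with β₇/LRT/p/FDR, control status, interface
metrics, tissue correlations, eQTL tagging fractions) are TSVs in
`demo_run/`, with parameters and SHA-256 checksums in `manifest.json` —
re-running the same config reproduces identical files.

The same stages are available as library calls (`simulate_cohort`,
`compute_attenuation`, `classify_attenuation`, `screen_pairs`,
`screen_phospho`, `extract_interface`, `harmonize_panel`, `build_blocks`,
…) and as per-stage CLI subcommands.

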