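# raresoil

A tested, reusable pipeline linking the diversity of rare versus abundant
soil taxa (archaea, bacteria, fungi, protists) to ecosystem
multifunctionality and community-assembly stochasticity. All stages run
end-to-end on a built-in synthetic data generator that emulates the study
design (228 samples along a latitude gradient, four rarefied community
tables, 16 ecosystem functions in four service groups), so nothing needs to
be downloaded.

## What it computes

- **core**: community/function/metadata table I/O (TSV/CSV, optional BIOM),
  seeded rarefaction (multivariate hypergeometric), relative abundances.
- **partition**: abundant (> 0.5%), intermediate, rare (< 0.05%)
  classification by dataset-level relative abundance, plus the two
  alternative published schemes (1%/0.1% and 0.1%/0.01%).
- **diversity**: richness, min-max standardization
  `STD = (X - Xmin) / (Xmax - Xmin)`, multidiversity (mean of the four
  groups' standardized richness).
- **multifunctionality**: 0–1 function standardization with inversion of
  "less is better" functions, averaging index, service-weighted index, and
  the first principal-coordinate axis of the standardized functions.
- **bef**: OLS biodiversity–multifunctionality regressions, Spearman
  diversity × function correlation matrix, the supporting-phylotype screen
  (rho > 0, P < 0.01), support summaries and the Wilcoxon rank-sum
  comparison of support breadth between abundant and rare phylotypes.
- **network**: abundant- and rare-taxa co-occurrence networks
  (|Spearman rho| > 0.6, Benjamini–Hochberg q < 0.001), per-node Pearson
  support scores versus multifunctionality, degree–support regressions,
  GraphML/GEXF export.
- **assembly**: abundance-weighted Bray–Curtis stochasticity ratio (ST)
  against a null model that preserves per-sample richness, draws membership
  proportionally to occupancy frequency, and fills abundances from the
  regional pool (1,000 randomizations by default); ST across rank bins of
  multifunctionality or multidiversity with polynomial trend fits.
- **windows**: moving-window (sizes 30/40) BEF slopes and ST along the
  latitude-ordered samples, with second-order polynomial slope-vs-ST trends.
- **simulate**: the synthetic study-design emulator with tunable couplings
  (`beta_rare`, `beta_abundant`), environmental-filtering strength
  (`beta_env`), and a ground-truth record for parameter-recovery scoring.

## CLI

Every stage is a subcommand sharing one YAML config; `all` runs the whole
pipeline. A minimal simulated run:

```yaml
# config.yaml
output_dir: out
seed: 1
simulation: {}        # empty block = full default design (228 samples)
n_null: 1000
window_sizes: [30, 40]
```

```sh
raresoil all --config config.yaml
raresoil simulate --config config.yaml      # dataset files only
raresoil diversity --config config.yaml     # one stage, composable
```

Outputs are TSVs (plus GraphML/GEXF networks) under `output_dir`, each with
a provenance header (version, master seed, config hash). Identical config
and seed reproduce every output byte-for-byte. Real data can be supplied
instead of the simulation block via an `inputs:` block pointing at the four
community TSVs, the function CSV (+ YAML schema sidecar), and the metadata
CSV.

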