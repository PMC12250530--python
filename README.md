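# fluxscreen

Expression-constrained genome-scale metabolic modeling, differential flux
statistics, and in-silico metabolite knockout screening — with a paired
pre/post metabolomics contrast and a fully synthetic, ground-truthed test
bed.

## What it does

Given a constraint-based metabolic model, a gene-expression matrix with
case/control labels, a kinetome (kcat) table and a nutrient medium, the
pipeline:

1. **bounds** — evaluates each reaction's GPR rule per sample (AND = min,
   OR = sum) and caps its flux at a Michaelis–Menten capacity
   `scale · kcat · enzyme_abundance`; the medium sets exchange uptake bounds
   and closes all unlisted uptakes (`fluxscreen model`);
2. **FVA** — runs flux variability analysis per sample and summarizes each
   reaction by its FVA maximum (or midpoint, `fva_summary: mid`);
3. **differential flux** — log2 fold changes plus an empirical-Bayes
   moderated t-test implemented from the published shrinkage formulas;
   significance gate `p < 0.05` and `|log2fc| > 0.2` (`fluxscreen diff`);
4. **pathway DA scores** — per subsystem,
   `(n_up − n_down) / n_reactions`, with a bootstrap-without-replacement
   null (size-matched uniform reaction subsets) and BH FDR
   (`fluxscreen da`);
5. **metabolite knockout screen** — all-against-all metabolite knockouts
   (consumption blocked, production left open) yield an effect matrix
   M(KO) ∈ {−1,0,+1}; the metabolite effective score
   `MES_i = Σ_j M[i,j] · sign(log2fc_j) · L_j` is tested against a normal
   background; MES > 0 at FDR < 0.05 ⇒ agonist (supplementation
   candidate), MES < 0 ⇒ antagonist (`fluxscreen ko`);
6. **paired metabolomics** — per-subject paired log2 changes
   (post − baseline) contrasted between patient and control groups with the
   same moderated machinery (`fluxscreen dm`).

Several conventions the upstream methods literature leaves open (OR = sum
GPR aggregation, the FVA statistic fed to the statistics, consumption-only
knockout semantics, the L_j indicator in the MES sum) are reconstructions;
each has a config switch and is flagged in the module docstrings.

## CLI

```bash
# emit a self-contained synthetic study (model, expression, kinetome,
# medium, paired metabolomics, ground truth, ready-made config)
fluxscreen simulate --outdir study/ --seed 1

# run the whole chain; outputs are TSVs with provenance headers and are
# byte-identical across reruns with the same config + seed
fluxscreen all --config study/config.yaml --outdir results/

# or stage by stage
fluxscreen model --config study/config.yaml --outdir results/
fluxscreen diff  --config study/config.yaml --outdir results/
fluxscreen da    --config study/config.yaml --outdir results/
fluxscreen ko    --config study/config.yaml --outdir results/
fluxscreen dm    --config study/config.yaml --outdir results/
```

Config keys (YAML): `model`, `model_format` (`cobra-json` | `tabular`),
`expression`, `labels`, `kinetome`, `medium`, `metabolomics`, thresholds
(`p_threshold` 0.05, `fc_threshold` 0.2, `fdr_threshold` 0.05,
`da_threshold` 0.2), `B` (bootstrap draws), `seed`, `fva_summary`,
`l_weight` (`indicator` | `abs_log2fc`), `robust_fit`, `scale`,
`default_kcat`, `ko_reference` (`mean` | `control` | `case`).

## Model formats

- **cobra-json** — the cobrapy JSON schema (round-trips through
  `cobra.io.load_json_model`).
- **tabular** — a directory of `metabolites.tsv`, `reactions.tsv`
  (stoichiometry as `A[c]:-1;B[c]:1`, GPR as infix boolean text) and
  `genes.tsv`; hand-editable for fixtures.

Metabolite ids may use `[c]` or `_c` compartment suffixes; both are
normalized to `[c]`.

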