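# seedspan

Comparative seed-longevity analysis for controlled-ageing experiments:

* **Viability-curve fitting** — binomial maximum-likelihood probit fits of the
  seed viability equation (viability in normal equivalent deviates declining
  linearly with ageing time) and a declining-logistic alternative, with AIC
  model choice, delta-method standard errors and a *p50* defined as the time
  to reach 50 % of the *initial* fitted viability.
* **Trait table** — a validated species-level table (taxonomy, endosperm
  class E/N, dormancy class ND/PD/PY, *p50* ± SE, optional continuous seed
  traits), including the packaged 39-species calcareous-grassland study table
  used as a fixture throughout.
* **Phylogeny** — taxonomy-based tree construction (order/family/genus
  nesting with polytomies), node dating by even age interpolation between
  nodes of known age, Newick I/O, and phylogenetic covariance extraction with
  Pagel's lambda branch-length transformation.
* **Phylogenetic signal** — Pagel's λ (ML with likelihood-ratio tests),
  Blomberg's K (with MSE-based randomization), Fritz–Purvis D for binary
  traits (with random and threshold-Brownian reference simulations).
* **Comparative models** — non-phylogenetic GLS and PGLS (λ jointly
  ML-estimated) candidate sets, AICc ranking, Akaike weights, full model
  averaging with unconditional SEs, plus one-way ANOVA / Tukey HSD group
  comparisons.
* **Synthetic data** — generators for germination time-courses, dated trees,
  Brownian continuous traits, threshold-liability binary traits and complete
  study-like datasets with known ground truth.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact group
means/ANOVA statistics computable from the packaged study table, and the
statistical calibration properties (grid-search oracle equivalence of the
probit fit, p50 recovery, λ/K/D calibration under Brownian and shuffled
traits, full-pipeline effect-sign recovery). The full suite takes ~3 minutes
on one CPU.

## CLI

```bash
# fit survival curves from a long-format CSV (species, time_days, n_tested, n_germinated)
seedspan fit-viability --input timecourses.csv --model probit --out fits.csv

# build + date the taxonomy tree from a trait table
seedspan tree --traits table1.csv --ages node_ages.csv --out tree.nwk

# phylogenetic signal of one trait column
seedspan signal --tree tree.nwk --traits table1.csv --stat lambda --trait-column p50 \
    --nperm 1000 --seed 1 --out signal.json

# candidate (P)GLS models, AICc ranking and model averaging
seedspan models --traits table1.csv --tree tree.nwk --phylo --out models.json

# group summaries, ANOVAs and Tukey tests on the packaged study table
seedspan reproduce-study --out groups.json

# synthetic study with known truth
seedspan simulate --seed 1 --out-dir sim/

# full pipeline from a YAML config
seedspan run --config pipeline.yaml --out-dir out/
```

A pipeline config looks like:

```yaml
stages: [tree, signal, models, groups]   # viability too, when timecourses given
seed: 1
n_perm: 1000
# timecourses: timecourses.csv
# traits: my_traits.csv       # defaults to the packaged 39-species table
# node_ages: node_ages.csv    # defaults to the packaged age table
```

## Data notes

The packaged `table1.csv` carries the 39-species study table verbatim
(species, family, order, endosperm, pretreatment, dormancy, germination
temperature, fitted *p50* ± SE, longevity rank). `node_ages.csv` provides
approximate, user-replaceable crown ages (Myr) for the 13 orders and 18
families involved; since the original dated megatree is not redistributed,
phylogenetic quantities are reproducible qualitatively, not digit-for-digit.
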