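# mitobayes

A Bayesian risk model of Alzheimer's disease (AD) progression as a function of
diet type, mitochondrial-dynamics biomarkers (OPA1, MFN1, MFN2, DRP1, FIS1)
and lifestyle factors. The package combines:

- **`network_model`** — the model's static structure: a prior-probability
  table (per-marker abnormality rates and age-bracket risks), a signed
  directed influence graph (validated acyclic), and per-diet odds-scale
  modifiers. All loadable/overridable from a YAML config.
- **`cohort`** — a seeded Monte-Carlo cohort simulator: uniform integer age
  on [30, 95], uniform diet over {HFO, HL, starv, CR, none}, one Bernoulli
  0/1 draw per marker at its diet-adjusted prior (optionally conditioned on
  earlier markers via CPT overrides), derived fusion/fission flags, and a
  per-patient progression probability.
- **`bayes`** — uniform likelihood, Pareto conjugate prior with the
  closed-form update `Pareto(max(b, max y), K + n)`, discrete posterior
  normalization, and counting-based conditional-probability estimation with
  a binomial Monte-Carlo error.
- **`cases`** — a deterministic evidence-to-risk cascade reproducing the five
  published reference patient profiles exactly.
- **`io` / `cli`** — cohort CSV round-tripping, JSON run reports, and the
  `mitobayes` command-line tool.

## CLI

```sh
# reference five-row case table (stdout or --out file)
mitobayes table2

# seeded cohort simulation, CSV + optional JSON report
mitobayes simulate --n 1000 --seed 7 --out cohort.csv --report report.json

# evaluate one evidence pattern (unlisted markers default to 0)
mitobayes evaluate --evidence "db=1,ht=1,dp=1,diet=HFO,age=63"

# conditional probability with Monte-Carlo error over a cohort CSV
mitobayes estimate --cohort cohort.csv --evidence "diet=HL" --outcome "AD>=0.5"

# conjugate Pareto update under uniform observations
mitobayes pareto-update --b 1 --k 2 --obs 0.5 --obs 0.8
```

The cohort CSV header is exactly
`id,atp,opa1,mfn1,mfn2,drp1,fis1,db,os,ht,ob,dp,pa,diet,age,fusion,fission,AD`;
the "no diet" category serializes as the token `0`.

## Configuration

`mitobayes ... --config model.yaml` accepts a YAML document with any subset
of the sections `priors`, `network`, `diet_modifiers`, `simulation`,
`case_rule`; missing sections fall back to the bundled defaults. Example:

```yaml
priors:
  markers: {os: 0.30}          # merge-override a single marker prior
  default: 0.5                 # prior for markers without a table entry
  age_brackets:
    - {min: 30, max: 64, probability: 0.04}
    - {min: 65, max: 74, probability: 0.15}
    - {min: 75, max: 84, probability: 0.43}
    - {min: 85, max: 95, probability: 0.38}
network:
  cpt_overrides:               # 2^k-row parent-conditioned tables
    os:
      parents: [db]
      table: {'0': 0.1, '1': 0.6}
diet_modifiers:                # odds-scale multipliers, 1 = identity
  HL: {fis1: 2.0, ob: 2.0, mfn2: 0.5}
simulation: {n: 1000, seed: 0, diets: [HFO, HL, starv, CR, none]}
case_rule:
  marker_priority: [opa1, mfn2, mfn1, drp1, fis1]
  lifestyle: [ht, dp, ob, pa, os]
  no_diet_baseline: 0.743
```

`mitobayes.write_config` / `load_config` round-trip this format exactly.

## Case-evaluation rule

The deterministic cascade maps an evidence pattern to a probability:

1. any abnormal mitochondrial marker → the table prior of the
   highest-priority abnormal one;
2. otherwise, no diet intervention → the fixed baseline (0.743);
3. otherwise, any positive lifestyle marker → the largest prior among them;
4. otherwise → the age-bracket risk.

This is the minimal deterministic rule consistent with all five reference
rows; the priority order among markers is under-determined by those rows and
is configurable, as is every other element. Note that the no-diet baseline is
a constant by necessity: the reference profile it reproduces has no abnormal
marker, so no marker lookup can yield its probability.

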