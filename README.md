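# symbiopop

Quantitative toolkit for the population dynamics of an induced
endosymbiosis propagated through fungal spores: a deterministic
recursion model of the bacteria-positive spore fraction, a stochastic
simulator of the FACS-selection serial-passage experiment, inference from
count data, voxel-based bacterial-load quantification from 3D image
stacks, and a synthetic-data generator so the whole pipeline is testable
without any external data.

## What it computes

- **`symbiopop.model`** — the per-round recursion
  `p_x = (p·g·p0) / (p·g + (1−p)·e)` for the positive fraction under
  propagation without selection, the fitness index `p·g`, fixed points,
  the small-`p` decline factor `g·p0/e`, and the wash-out round relative
  to the propagation threshold (1/100,000 by default; detection limit
  1/1,000,000).
- **`symbiopop.simulate`** — finite-population, seedable simulation of the
  serial-passage design (measure → sort → plate → germinate → sporulate),
  with optional positive FACS sorting, sort impurity, and load-dependent
  germination. Its large-population mean reduces to the recursion.
- **`symbiopop.inference`** — proportion estimates with Wilson /
  Clopper–Pearson intervals, germination success and delayed-germination
  fractions, per-line fitness tables, transmission-parameter estimation
  from round-0 counts, log10-scale model-fit RMSE with censoring, the
  ≥50 % allele-frequency sweep filter, Spearman sweep–fitness
  correlation, Welch's unpaired t-test and the exact Wilcoxon
  matched-pairs signed-rank test.
- **`symbiopop.imaging`** — bacterial load as above-threshold voxel
  volume (Otsu default threshold with manual override, 26-connected
  components) and deterministic low/medium/high intensity binning.
- **`symbiopop.synth`** — generators for measurement tables, allele
  sweep tables, FACS intensity lists, and rod-in-ellipsoid 3D spore
  stacks with constructed ground truth.
- **`symbiopop.io` / `symbiopop.cli`** — strict CSV/YAML/JSON schemas
  (fractions internally, `_pct` columns converted exactly once at the
  file boundary) and the command-line interface.

## CLI

```sh
# deterministic prediction + wash-out round
symbiopop predict --g 0.88 --e 0.69 --p0 0.29 --p-init 0.29 --rounds 10 --threshold 1e-5

# first round below threshold only
symbiopop washout --g 0.88 --e 0.69 --p0 0.29 --p-init 0.29

# stochastic serial passage from a YAML config (explicit seed required)
symbiopop simulate --config run.yaml --seed 1 --out sim_out/

# estimate (g, e, p0) and model-fit error from a measurement table
symbiopop fit --measurements measurements.csv --out fit.json

# generate a synthetic experiment from a truth config
symbiopop synth --truth truth.yaml --seed 1 --out data/

# quantify bacterial load of every TIFF stack in a directory
symbiopop loadquant --stacks stacks/ --voxel 0.2,0.1,0.1 --out load.csv

# fitness table + trajectory figure for a run directory
symbiopop report --in data/ --out report/
```

A minimal `run.yaml` for `simulate`:

```yaml
params: {g: 0.88, e: 0.69, p0: 0.29}
sim:    {p_init: 0.29, n_rounds: 5, selection_mode: none}
seed: 1
```

Unknown keys are rejected; every stochastic command needs a seed; output
files embed the config hash and seed, and re-running a manifest
reproduces outputs byte-identically.

## Measurement CSV schema

Columns, exactly:
`line_id, round, facs_analyzed, facs_positive, wells_sorted_pos,
germinated_day1_pos, germinated_day2_pos, wells_sorted_neg,
germinated_day1_neg, germinated_day2_neg` — the negative-arm trio is
optional. Percent-valued columns must be suffixed `_pct` and are
converted to fractions on read. Allele tables use
`mutation_id, round, frequency, present_in_ancestor`.

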