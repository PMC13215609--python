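# chronomem

Desk-scale pipeline linking image "processing speed" — the collapse rate of
a recurrent conv net's softmax entropy — to simulated time-perception and
recognition-memory behavior, with the full inference stack needed to analyze
such experiments.

The package has six parts:

| module | what it does |
| --- | --- |
| `chronomem.entropy_engine` | untrained 8-layer recurrent conv net (numpy); per-image Shannon-entropy traces over 8 timesteps; fixture-image generator |
| `chronomem.speed_model` | power-curve fit `E(T) = A·T^B + C` (multi-start NLS), speed ordering on `A`, entropy-threshold duration-categorization proxy |
| `chronomem.stimulus_sampler` | three sampling strategies over an (image, memorability, A) table; 7 equal-width bins, 392 images, stratified 196/196 test–foil split |
| `chronomem.synthetic_behavior` | seeded generators: cohorts, log-spaced 300–900 ms duration grid, logistic-choice and inverted-U bisection sessions, lognormal RTs with outliers, old/new recognition, synthetic score tables |
| `chronomem.inference` | per-subject 3-SD log-RT filter, Laplace-approximate mixed logistic fits, nested LR tests, binned psychometric surfaces (7×7, 11×1), weighted quadratic inverted-U fit, recognition summaries, repeated-measures ANOVA, pairwise contrasts |
| `chronomem.io_cli` | CSV schemas, YAML run configuration, umbrella pipeline, `chronomem` CLI |

Everything runs on one CPU from synthetic data; no external datasets or
model weights are required.

## CLI

```bash
chronomem init-config --out run.yaml         # commented config template
chronomem run-all --config run.yaml --seed 1 --out-dir out/
```

`run-all` executes score-table → sample → simulate → analyze, persisting
every intermediate (scores.csv, manifest.csv, trials.csv, recognition.csv,
coefficients.csv, lr_tests.csv, surface.csv, inverted_u.csv,
recognition_summary.csv) plus a manifest.json with the seed, config hash and
per-stage row counts. The stages are also exposed individually:

```bash
chronomem make-scores --n-images 5000 --seed 1 --out scores.csv
chronomem sample --strategy slow --scores scores.csv --seed 2 --out manifest.csv
chronomem simulate --manifest manifest.csv --n-subjects 20 --seed 3 --out-dir sim/
chronomem analyze --trials sim/trials.csv --scores scores.csv \
    --recognition sim/recognition.csv --manifest manifest.csv --out-dir results/
```

Image scoring works on any directory of PNG/JPEG files:

```bash
chronomem score-images --images imgs/ --seed 1 --out scored.csv
chronomem fit-speeds --traces scored.csv --out refit.csv
```

## Notes on conventions

- Entropy is measured in nats; the admissible range is [0, ln K].
- Declining traces have `A < 0`; more negative `A` = faster collapse.
- Covariates are coded identically in the generator and the fitter:
  memorability centered on the stimulus-set mean, `A` z-scored, log-duration
  z-scored over the grid — so simulated coefficients are recovered on the
  generating scale.
- All generators take explicit seeds; the pipeline expands one master seed
  into independent per-stage substreams.
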