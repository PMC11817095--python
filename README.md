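# dentage

Automated dental age estimation from panoramic radiographs (OPGs) and
numeric patient records.

In forensic odontology and pediatric dentistry, a subject's chronological
age is estimated from the developmental stage of their teeth. Manual
methods (Demirjian, Willems, Cameriere staging) are slow and
observer-dependent; this package implements a fully automatic pipeline:

1. **Dual CNN feature extraction** — a 2-D convolutional network embeds
   the OPG (the region containing the seven left-mandibular permanent
   teeth) into a 128-dimensional feature vector, and a 1-D convolutional
   network embeds the numeric record fields into another 128 features.
   Both are trained as age-bin classifiers with a softmax cross-entropy
   head that is discarded after training.
2. **Feature fusion** — per-patient concatenation of the two feature
   vectors (early fusion, 256 features at the default widths).
3. **MG-RF regression** — a Modified Genetic–Random Forest: a
   generational genetic algorithm (population 20, 50 generations,
   tournament selection, crossover 0.8, mutation 0.1, elitism) searches
   jointly over a random-forest hyperparameter grid
   (max_depth, mtry rule, leaf/split minima, n_estimators ∈
   {200, …, 2000}) **and** a per-tree retention bitmask that prunes the
   fitted ensemble. Fitness is validation MSE of the masked ensemble;
   prediction is the mean over retained trees, ŷ = (1/|R|) Σ_{t∈R} f_t(x).
4. **Evaluation** — SD of residuals, MAE, MSE, RMSE = √MSE, and
   R² = 1 − SS_res/SS_tot, all in years on the original age scale.

Because clinical OPG datasets are private, the package ships a synthetic
cohort simulator with a known, recoverable age signal: ages 6–15 with
sex-specific means (10.94 male / 11.1 female), images whose rendered
tooth development grows monotonically with (dental) age, and record
fields linear in age plus Gaussian noise. Every stage of the pipeline is
tested against this simulator; see `docs/methods.md` for the model and
its limits.

## Worked example

Simulate a 600-patient cohort and run the full pipeline at the package's
desk-scale configuration (64×64 images, narrowed CNN, reduced tree grid;
see `dentage.pipeline.desk_scale_config`):

```python
import pathlib, tempfile
from dentage import CohortConfig, generate_cohort, write_cohort
from dentage.pipeline import desk_scale_config, run_pipeline

root = pathlib.Path(tempfile.mkdtemp())
cohort = CohortConfig(n_patients=600, rng_seed=7)
records, images = generate_cohort(cohort)
manifest = write_cohort(records, images, root / "cohort")

report = run_pipeline(desk_scale_config(manifest, root / "run", seed=7))
print(report.to_json())
```

Output (about a minute on one CPU):

```json
{
  "mae": 0.27479429856374693,
  "mse": 0.1155294531666855,
  "n": 120,
  "r2": 0.9721460479156943,
  "rmse": 0.33989623882397624,
  "rmse_mse_consistent": true,
  "sd_of_errors": 0.3370516024986754
}
```

Reading this: on the 120 held-out test patients (20% of 600), predicted
age is off by 0.27 years on average (MAE), the residual spread is 0.34
years (RMSE, equal to √MSE — the `rmse_mse_consistent` flag verifies that
identity), and the model explains 97% of the age variance (R²). The MAE
sits just above the simulator's irreducible floors (0.75-year
inter-individual dental-timing spread on the image side, unit-SD field
noise on the record side) — the fused model integrates both modalities.

The run directory (`root / "run"`) holds the artifacts: feature CSVs,
`model_summary.json` (decoded hyperparameters, retained-tree indices,
feature ranking, GA history), `predictions_test.csv`, `report.json`,
a config snapshot that reproduces the run, and a stage-timed log.

### Command line

The same flow is scriptable via the `dentage` CLI:

```sh
dentage simulate --out cohort/ --seed 7 --n-patients 600
dentage run-all  --config pipeline.yaml --seed 7 --out run/
dentage ablate   --config pipeline.yaml --seed 7 --out ablation/
dentage evaluate --predictions run/predictions_test.csv
```

plus stage-wise subcommands (`preprocess`, `extract`, `fuse`, `fit`,
`predict`) that exchange CSV feature files. `pipeline.yaml` mirrors
`PipelineConfig` (write one with
`yaml.safe_dump(desk_scale_config(...).to_dict())`).

### Ablations

`dentage ablate` / `run_ablation` evaluates six configurations on one
shared test split: the full fused model, each modality removed, late
fusion without concatenation (averaging two single-path models), and
each single path alone. On the synthetic cohort the fused model attains
the lowest MAE, and the ordering full < late-fusion < weaker single path
mirrors the usual multimodal ablation pattern.

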