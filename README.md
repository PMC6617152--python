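# ddspls

Multi-block **data-driven sparse PLS** for biomarker panel selection, with
leave-one-out model selection, univariate screening statistics, a synthetic
multi-block data generator, and a command-line pipeline.

The estimator selects covariates by soft-thresholding each block's
cross-covariance with the response at a data-driven threshold (chosen so that
at most `L0` covariate columns survive across all blocks), extracts `R`
components per block by SVD without deflation, aggregates them through
second-level "super-weights", and regresses the standardized response on the
shared super-components through the Moore-Penrose pseudo-inverse. The two
hyper-parameters `(R, L0)` are chosen by minimizing the mean leave-one-out
MSEP, reported on the standardized response scale so that 1.0 is the
mean-prediction reference level.

## Library quick start

```python
from ddspls import (study_preset, generate_multiblock, grid_search,
                    fit_ddspls, build_selection_report, pearson_screen)

data, truth = generate_multiblock(study_preset(seed=1))
screen = pearson_screen(data, threshold=0.55)          # |r| >= 0.55 retained
cv = grid_search(data, R_values=[1, 2], L0_values=range(1, 11))
model = fit_ddspls(data, *cv.best)
report = build_selection_report(model, data, cv)
print(report.to_frame())      # selected biomarkers, block of origin, signs
```

Real data are read from one CSV per block plus a response CSV (header row,
first column = individual ID; rows matched by ID) via `read_block_dataset`,
or from a single wide CSV plus a block map via `read_wide_dataset`.

## Command line

```bash
# synthetic dataset emulating the 5-muscle / 20-biomarker design
ddspls simulate --preset study --seed 1 --out simdata/

# full pipeline from a YAML config (see ddspls/cli.py docstring for the schema)
ddspls fit --config config.yaml --out results/

# correlation screen only
ddspls screen --config config.yaml --out results/

# rebuild a report from a saved model
ddspls report --model results/model.json --response simdata/response.csv \
    --blocks GB=simdata/GB.csv,TB=simdata/TB.csv --out report/
```

Exit codes: 0 success, 2 schema/alignment/missing-data errors, 3 degenerate
input, 4 no signal.

## Layout

- `src/ddspls/datasets.py` — multi-block data model, CSV I/O, standardization
- `src/ddspls/synthetic.py` — planted-factor generator and the study preset
- `src/ddspls/core.py` — soft-thresholding, λ selection, SVD weights,
  super-weights, pseudo-inverse regression, NIPALS oracle
- `src/ddspls/model_selection.py` — LOO MSEP and (R, L0) grid search
- `src/ddspls/screening.py` — Pearson screens and one-way ANOVA
- `src/ddspls/report.py` — selection reports, R², plots
- `src/ddspls/cli.py` — `simulate` / `screen` / `fit` / `report` subcommands
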