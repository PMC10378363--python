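# ramandx

Raman spectral preprocessing and PCA–LDA chemometric classification of
fibroblast cell spectra, with a synthetic dataset generator for end-to-end
testing.

The pipeline discriminates three cell classes — `NFC` (normal), `NIH/3T3`
(precancerous), and `MBM-T` (cancerous) — from 600–1800 cm⁻¹ Raman spectra
measured at up to three sites per cell (center, cytoplasm, membrane):

1. **spectra_io** — two-column spectrum tables, dataset manifests, and the
   four per-cell analysis databases: site-averaged (I) and single-site
   center/cytoplasm/membrane (II/III/IV).
2. **preprocess** — cut to 1800–600 cm⁻¹, 5-point Savitzky–Golay smoothing,
   iterative (×5) anchored-minima baseline correction in two sub-regions
   (fixed anchors at 1800/1750/1720/1560/1530/1490 cm⁻¹ above 1200 cm⁻¹;
   50 equal-range minima below), and vector normalization with a final
   minimum-to-zero shift.
3. **chemometrics** — PCA feature extraction (fit on training data only) and
   two-class LDA by minimum Mahalanobis distance under a pooled covariance
   with uniform priors; the four binary tasks with their positive-class
   conventions.
4. **evaluation** — stratified, cell-grouped 5-fold cross-validation;
   ACC/SE/SP/PPV/NPV from fold-summed confusion counts; accuracy-vs-PC-count
   curves with plateau-based PC selection; four-wavenumber-range sub-range
   analysis; class-mean difference spectra.
5. **synthetic** — labelled synthetic datasets with the study's design shape
   (457 cells, 997 site spectra), Lorentzian band spectra from a 35-band
   literature catalogue, fluorescence background, and calibrated
   class-dependent intensity effects at the known difference bands.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; its
ordering-recovery test simulates twenty full-size datasets and takes a few
minutes on one CPU. Everything else finishes in seconds.

## CLI

```sh
ramandx simulate  --out sim/ --seed 1 --write-files     # synthetic dataset
ramandx import    --manifest sim/manifest.csv --out ds.json
ramandx preprocess --in ds.json --out pp.json [--dump-baseline dir/]
ramandx evaluate  --in pp.json --task normal-vs-abnormal --database I \
                  --auto-pcs --max-pcs 25 --k 5 --seed 0
ramandx evaluate  --in pp.json --task NFC-vs-MBM-T --subranges
ramandx scores    --in pp.json --database I --out scores.csv   # PC1-PC2 table
ramandx fit       --in pp.json --task NFC-vs-MBM-T --n-pcs 5 --out model.json
ramandx predict   --model model.json --in pp.json --out preds.csv
```

Task ids: `normal-vs-abnormal`, `NIH/3T3-vs-MBM-T`, `NFC-vs-NIH/3T3`,
`NFC-vs-MBM-T`. The abnormal/cancerous side is always the positive class;
`NIH/3T3` is positive against `NFC`.

Datasets travel as a single JSON container (wavenumber grid + per-cell site
spectra + provenance); spectrum files are plain two-column text tables;
manifests are CSV with columns `file,cell_id,class,site`.

## Library example

```python
from ramandx import (
    CVConfig, DatabaseSpec, SimConfig, accuracy_vs_pcs, build_database,
    generate_dataset, make_task, run_cv, select_n_pcs,
)
from ramandx.preprocess import preprocess_manifest

manifest = generate_dataset(SimConfig(seed=1))
entries = build_database(preprocess_manifest(manifest), DatabaseSpec("I"))
task = make_task("normal-vs-abnormal")
curve = accuracy_vs_pcs(entries, task, CVConfig(seed=0), max_pcs=25)
n = select_n_pcs(curve)                      # plateau-based PC count
result = run_cv(entries, task, n, CVConfig(seed=0))
print(result.metrics.acc, result.metrics.acc_std)
```
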