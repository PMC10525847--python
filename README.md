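# fundusroi

Landmark-anchored region-of-interest (ROI) extraction and label-routed
multi-label disease classification for widefield retinal images.

The pipeline localizes the optic disc and the macula, crops two square ROIs
whose edge lengths are multiples (`alpha`, `beta`) of the optic-disc box
diagonal `d`, and routes six binary disease targets to three classification
branches:

| branch           | region        | targets        |
|------------------|---------------|----------------|
| `od_gs`          | optic-disc ROI (edge `alpha*d`, default 3d) | GS |
| `mac_erm_amd`    | macula ROI (edge `beta*d`, default 6d)      | ERM, AMD |
| `full_dr_rb_rvo` | entire image  | DR, RB, RVO    |

A whole-image all-six-label baseline (`baseline_full6`) is included as the
ablation comparator. Per-class decision cut-offs are tuned to maximize
sensitivity x specificity, and evaluation reports one-vs-rest
AUC/accuracy/sensitivity/specificity, pooled micro-averages, a derived
"Normal" (all-negative) row, repeated-run Student-t confidence intervals, and
a single-label misclassification matrix.

Because clinical widefield datasets are rarely redistributable, the package
ships a synthetic scene generator (`fundusroi.synthdata`) producing circular
retinal fields with a bright optic disc, a darker macula, and lesions whose
spatial regime is disease-specific (global scatter, macula-concentrated, or
peridiscal). Every downstream stage — detection (via a ground-truth-backed
oracle detector), ROI geometry, training, threshold tuning, evaluation — runs
end to end on this generator with no external data.

The classification backbones are deliberately small, fully seeded NumPy
networks (dense layers + Adam) behind a registry, so the complete training
loop is deterministic and runs on one CPU in seconds; heavier backbones can
be registered behind the same interface.

## CLI

```bash
fundusroi generate --out data/ --n-images 200 --seed 0
fundusroi detect --manifest data/manifest.csv --out detections.json
fundusroi extract-rois --manifest data/manifest.csv --alpha 3 --beta 6 --out rois/
fundusroi split --manifest data/manifest.csv --ratio 0.9 --out splits/
fundusroi run-all --config config.yaml
fundusroi ablate-roi --config config.yaml --multipliers 2,3,4,5,6,entire --out sweep.csv
fundusroi ablate-backbone --config config.yaml --backbones tiny-mlp,linear --out backbones.csv
fundusroi roi-advantage --workdir scratch/adv
```

Minimal `config.yaml` for `run-all`:

```yaml
workdir: scratch/run1
n_images: 200
synth:
  image_size: 128
  seed: 0
branches:
  od_gs: {epochs: 10, input_size: 32}
  mac_erm_amd: {epochs: 10, input_size: 32}
  full_dr_rb_rvo: {epochs: 10, input_size: 32}
seeds: [0]
```

Re-running the same config reproduces `report.json` byte for byte.

## Layout

- `src/fundusroi/synthdata.py` — synthetic scene/dataset generator and manifest IO
- `src/fundusroi/landmarks.py` — detections, proposal filtering (boundary + IoU suppression), landmark selection, oracle detector
- `src/fundusroi/roi.py` — square ROI extraction anchored to the disc diagonal
- `src/fundusroi/classify/` — label routing, augmentation/preprocessing, backbones, branch training, stratified splitting
- `src/fundusroi/evaluate.py` — AUC, cut-off tuning, micro-averages, CIs, significance, ROC export, misclassification matrix
- `src/fundusroi/pipeline.py` — orchestration, ablation harnesses, ROI-advantage experiment
- `src/fundusroi/cli.py` — `fundusroi` console entry point
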