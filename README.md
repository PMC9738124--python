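# pygleason

Multi-scale patch-cascade grading of digitized biopsy-like images, with a
seeded synthetic-slide generator so the whole pipeline is testable offline.

The pipeline:

1. **synthetic slides** — procedural histology-like images with per-pixel
   ground-truth labels (0 = background, 1–5 = tissue pattern classes);
   contiguous class regions, configurable prevalence, fully seeded.
2. **preprocess** — slide-wide histogram equalization (luminance or
   per-channel), per-patch unsharp-mask edge enhancement, intensity tissue
   mask.
3. **tiling** — per pyramid level (patch sizes 100/75/50, 20 % shift) one
   unshifted grid plus 4 shifted grids in each of X, Y and diagonal
   directions: 13 complete tilings per level, 39 in total. Training patches
   are selected from the unshifted grid when the modal tissue label equals
   the center-pixel label and the background ratio is ≤ 0.5.
4. **cascade** — per level, four binary classifiers resolve one label in 1–5
   ({1,2} vs {3,4,5}; 1 vs 2; 3 vs {4,5}; 4 vs 5). Backends: a pure-numpy
   tiny CNN (3×3 convs, max-pooling, dropout, two FC layers, cross-entropy,
   Adam, random-search tuning) and a ground-truth oracle test double.
   Class balancing subsamples every class to the rarest class's count.
5. **fusion & grading** — each patch paints its label over its pixels, so
   every pixel collects 39 votes; per-pixel majority vote (ties toward the
   lower label) yields the pattern map. The two largest malignant areas
   (labels 3–5) give the score (primary + secondary, 6–10) and the grade
   group (GG1–GG5, or Benign below a malignant-area threshold).
6. **evaluation** — confusion matrices, one-vs-rest precision/recall/F1,
   macro and support-weighted averages, ROC curves.

## CLI

```bash
pygleason synth --n-slides 4 --width 600 --height 600 --seed 1 --out slides/
pygleason train --slides slides/ --out model/           # 12 nodes, 3 levels
pygleason grade --model model/ --slide slides/slide_000 --out graded/
pygleason grade --backend oracle --slide slides/slide_000 --out graded_oracle/
pygleason eval --predictions preds.csv --out report/    # actual,predicted CSV
```

Configuration is YAML (`--config`); see `pygleason.config.RunConfig` for the
schema. Every command writes a `manifest.json` with config, seeds and
timings. Exit codes: 0 success, 2 validation error, 1 runtime failure.

## Layout

```
src/pygleason/
  synthetic.py    slide generator + PNG/JSON I/O
  preprocess.py   equalization, edge enhancement, tissue mask
  tiling.py       patch groups, training-patch selection
  nn.py           numpy CNN (forward/backward, Adam, early stopping)
  cascade.py      node specs, balancing, random search, routing
  fusion.py       vote stack, majority fusion, grading
  evaluation.py   confusion/metrics/ROC
  pipeline.py     end-to-end train/grade orchestration
  config.py       YAML run configuration
  cli.py          synth / train / grade / eval commands
```
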