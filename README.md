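# eafcn

Two-stage classification of Alzheimer's disease (AD) versus normal
cognition (NC) from 3D structural brain volumes, built around a
patch-trained fully convolutional network with optional external-attention
blocks, voxel-lattice disease-probability maps, MCC-driven region-of-interest
selection, and a small fusion MLP that combines imaging features with
age, sex and MMSE.

It is written for methods researchers who want the full pipeline —
architecture arithmetic, attention variants, dense inference, heatmap/ROI
logic, fusion, and evaluation — as inspectable, testable numpy code that
runs end-to-end on a laptop CPU using synthetic cohorts with planted,
localized disease contrast.  It is not a clinical tool.

## The method

**Stage 1.** An FCN of four blocks (3D conv → max-pool → batch-norm →
Leaky ReLU → dropout) and two convolution-realized FC layers classifies
47³ patches sampled uniformly from each subject's volume, with patch
labels inherited from the subject diagnosis.  The network's receptive
field is exactly the patch size (47 voxels per axis, cumulative stride 4),
so the trained model applies densely to a whole volume and yields a
lattice of softmax probabilities p(AD) — the disease probability map,
with lattice site *i* centered at voxel 23 + 4·*i*.

An attention block may be inserted after block 4:

- *self-attention* — query/key/value 1×1×1 projections, an N×N softmax
  attention matrix over the N feature-map pixels, and a learnable residual
  gain γ (initialized 0); quadratic cost in N;
- *external attention* — two learnable memories M_k, M_v of k units shared
  across samples, with either a plain column softmax or **double
  normalization** (column softmax then row-wise L1,
  α_ij = softmax_col(FM_kᵀ)_ij / Σ_k softmax_col(FM_kᵀ)_ik),
  which stops extreme feature values from dominating the attention map;
  linear cost in N.

**Stage 2.** Across the validation fold, thresholding each lattice site's
probability at 0.5 against subject labels gives a per-site confusion table
whose Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) forms a heatmap;
the top-k sites are the ROI.  A two-layer MLP then classifies subjects
from (A) ROI probabilities, (B) standardized demographics, or (C) both.
Evaluation is stratified five-fold cross-validation reported as
mean ± SD of accuracy, sensitivity, specificity, F1 and MCC.

All network code (3D convolution with FFT and GEMM paths, pooling,
batch-norm, dropout, attention, Adam) is a self-contained numpy core with
hand-written backprop, gradient-checked against finite differences.
See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Architecture arithmetic (these are the exact layer-table values):

```python
>>> from eafcn import fcn_spec_default, output_shapes, receptive_field
>>> receptive_field(fcn_spec_default())
47
>>> output_shapes(fcn_spec_default(), (1, 47, 47, 47))[:3]
[('input', (1, 47, 47, 47)), ('conv1', (20, 44, 44, 44)), ('pool1', (20, 43, 43, 43))]
```

The standard desk-scale study — synthetic cohort of 20 AD + 20 NC
subjects on 64³ volumes with one lesion sphere (radius 8, intensity
deficit 0.6) at voxel (24, 24, 24), three training seeds of the thin FCN
profile at 200 iterations each:

```python
>>> from eafcn.experiments import desk_study
>>> s = desk_study(seed=101, n_seeds=3, iterations=200, roi_k=10)
>>> s["per_seed"][0]["top_center"], s["per_seed"][0]["dist_to_lesion"]
((23.0, 23.0, 23.0), 1.7320508075688772)
>>> s["lesion_recovery_hits"], [p["val_accuracy"] for p in s["per_seed"]]
(3, [1.0, 1.0, 1.0])
>>> s["mean_mlp_accuracy"]
{'A': 1.0, 'B': 0.9166666666666666, 'C': 1.0}
```

Reading the numbers: in all three seeds the highest-MCC lattice site sits
1.7 voxels from the planted lesion center (the pipeline localizes the
planted contrast); validation patch accuracy reaches 1.0 (the patch
classifier finds the class signal); and held-out fusion accuracy is 1.0
for the imaging-feature modes while demographics alone reach 0.92 —
MMSE is informative but its class ranges touch, so mode B is slightly
below the imaging modes on this synthetic cohort.

The same pipeline is scriptable from the shell:

```bash
eafcn simulate  --seed 3 --out cohort/ --n-ad 20 --n-nc 20
eafcn train-fcn --seed 3 --data cohort/ --out run/ --variant ea-double --iterations 200
eafcn heatmap   --seed 3 --checkpoint run/fcn.npz --data cohort/ --out run/ --roi-k 10
eafcn crossval  --seed 3 --data cohort/ --out cv/ --variant ea-double
```

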