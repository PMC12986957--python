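# tidalcd

Bi-temporal change detection for intertidal mangrove imagery, for
remote-sensing and coastal-ecology practitioners who need to separate
genuine vegetation change from tide-driven pseudo-change.

Between two acquisitions of the same mangrove stand the tide moves: water
extent, waterline shape, wet-mud albedo and sun glint all change
dramatically while the ecosystem is stable. Plain image differencing fires
on all of it. `tidalcd` implements a dual-stream difference-modeling
network with deep-guided multiscale fusion for this setting:

- a shared-weight (siamese) residual encoder produces bi-temporal feature
  pyramids F¹ⱼ…F⁴ⱼ at strides {4, 8, 16, 32}, channels {64, 128, 256, 512};
- at every level a **dual-stream change fusion** block combines a
  connection branch (concat → 3×3 → 1×1) with a difference branch that
  turns the signed difference F_d = F₁ − F₂ into spatial gates
  W_j = σ(WtConv(DSConv(F_d ⊕ F_{jk}))) (via partial channel exchange,
  depthwise-separable and Haar-wavelet convolutions) and channel gates
  W_S = σ(Σₖ Ψₖ(pool F_d)), then fuses W_S ⊗ W_j ⊗ F_j;
- the two deepest fused levels yield a single-channel **guidance map**
  F_DFG = σ(Conv₁ₓ₁(SA(Conv₃ₓ₃(X³ ⊕ Up(Conv₁ₓ₁ X⁴))))) that gates the
  decoder: cross-scale fusion multiplies concatenated features by
  σ(F_DFG) + 1 ∈ (1, 2) and re-weights them with channel attention before
  grouped-attention refinement and a lightweight stride-4 change head;
- training minimizes L = L_focal + L_dice, built for the severe class
  imbalance of sparse change (α = 0.2, γ = 2 by default; the alternative
  published parameterization ships as a second preset);
- evaluation reports Pre, Rec, F1 and IoU from micro-averaged confusion
  counts, renders white/black/red/green error maps, and aggregates
  multi-seed runs as mean ± std.

Because the real UAV dataset is not redistributable, the package includes a
**synthetic tidal-scene generator**: height-field terrain, tide-dependent
water with glint, wet-mud and algal-film pseudo-change (never labeled), and
mangrove stands whose appearance/disappearance is the labeled change. The
full pipeline — data, training, evaluation, complexity accounting — runs on
one CPU with no downloads. The network, including its reverse-mode autodiff
engine, is implemented in numpy (see `docs/methods.md`).

## Worked example

```python
import tidalcd as tc

# 1. synthetic tidal scenes: 64 training, 8 validation, 16 test pairs (64 px)
params = tc.SceneParams(size=64, seed=1234, change_rate=0.3, noise_sd=0.04)
train = tc.generate_split(params, 64, split_idx=0)
val = tc.generate_split(params, 8, split_idx=1)
test = tc.generate_split(params, 16, split_idx=2)

# 2. a narrow model (stage widths 16..128) trained for 30 epochs
cfg = tc.TrainConfig(seed=1234, epochs=30, step_size=10,
                     model=tc.ModelConfig(base_width=16))
model = tc.ChangeDetectionNet(cfg.model, seed=cfg.seed)
hist = tc.train_model(model, train, cfg, val_samples=val)
model.load_state_dict(hist["best_state"])

# 3. evaluate against the plain image-difference baseline
mset, counts = tc.evaluate_model(model, test, cfg)
thr = tc.fit_difference_baseline(train)
base, _ = tc.evaluate_difference_baseline(test, thr)
print(f"trained model   F1 {mset.f1:.3f}  Pre {mset.pre:.3f}  "
      f"Rec {mset.rec:.3f}  IoU {mset.iou:.3f}")
print(f"diff. baseline  F1 {base.f1:.3f}  (threshold {thr:.3f})")

# 4. complexity of the published-width architecture
rep = tc.complexity_report(tc.ModelConfig())
print(f"published width: {rep.params_m:.2f} M params, "
      f"{rep.gflops:.2f} G FLOPs at 256x256")
```

prints (about two minutes on one CPU):

```
trained model   F1 0.572  Pre 0.654  Rec 0.507  IoU 0.400
diff. baseline  F1 0.349  (threshold 0.237)
published width: 38.09 M params, 12.84 G FLOPs at 256x256
```

The trained detector already beats thresholded differencing at this very
small scale because the scenes are built so that tidal pseudo-change is
radiometrically as strong as true change — the baseline cannot tell them
apart, the difference-gated network can. The test suite runs the same
comparison at larger scale (96 training pairs, 40 epochs), where the full
model reaches F1 ≈ 0.89 and also beats its own no-guidance ablation.

## Command line

```sh
tidalcd synthesize data/tides --size 128 --n-train 200   # make a dataset
tidalcd train data/tides --out runs/a --epochs 50        # train
tidalcd eval runs/a/checkpoint.npz data/tides --split test --error-maps maps/
tidalcd predict runs/a/checkpoint.npz A.png B.png --out change.png
tidalcd complexity --backbone resnet18                   # params / FLOPs
tidalcd aggregate run1.json run2.json run3.json          # mean ± std
```

Datasets use the common `A/ B/ label/` directory layout (8-bit PNG, labels
0/255); masks, predictions and error maps are PNG; metrics are JSON; logs
are line-delimited JSON; every artifact records its seed and config hash.

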