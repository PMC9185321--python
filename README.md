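# fallgan

Unsupervised fall detection in depth/thermal video via a
future-frame-prediction GAN with encoded-feature angular scoring.

A convolutional encoder–decoder generator is trained **only on normal
activity**: it receives 8 consecutive frames and reconstructs the 8-frame
window shifted 4 frames forward, so its last 4 outputs predict unseen
frames. A patch-based least-squares discriminator, a gradient-difference
loss and an optical-flow consistency loss sharpen the predictions. At
inference, the reconstructed sequence is fed back through the encoder and
the anomaly score is the angle θ between the bottleneck encodings of the
reconstructed and the authentic sequences — a scoring scheme that is
robust to depth-sensor hole pixels and frame jitter, where per-pixel
reconstruction error is not. Falls, being fast unusual motions the model
never saw, produce large angles.

The package is pure numpy/scipy: the networks, losses and Adam training
loop run on a small reverse-mode autograd engine (`fallgan.nn`) with
im2col convolutions, so no deep-learning framework is required. A
synthetic depth-video simulator (bright elliptical subject, smooth
walks/sits, rapid falls, hole dropouts, jitter, optional occluding
furniture) makes the full pipeline trainable and verifiable on one CPU.

## Layout

| module | role |
| --- | --- |
| `fallgan.video_io` | PNG frame-stack clips, labels, 8-in/8-target windowing |
| `fallgan.preprocess` | depth hole filling (iterative diffusion), resize, [−1,1] normalization |
| `fallgan.synthetic` | seeded synthetic fall/ADL clip generator and dataset builder |
| `fallgan.nn` | minimal autograd: conv2d, upsampling, Adam, gradcheck-verified |
| `fallgan.networks` | generator (encoder–decoder, exposed bottleneck), patch discriminator, Horn–Schunck flow |
| `fallgan.losses` | L2, gradient-difference, optical-flow and least-squares adversarial losses |
| `fallgan.training` | alternating GAN training, lr schedule, bit-exact checkpoint/resume |
| `fallgan.scoring` | angular score, window→frame mapping, per-clip normalization, threshold grid search |
| `fallgan.evaluation` | frame-level AUC, score gap Δs, confusion counts, reports |
| `fallgan.config` / `fallgan.cli` | validated YAML config (desk/paper presets), `fallgan` CLI |

## CLI

```bash
# generate a synthetic dataset (normal-only train split + mixed test split)
fallgan synth --out data/ --seed 1

# train on the normal-only split
fallgan train --data data/manifest.yaml --out runs/desk

# score a clip (raw θ online, or per-clip min–max normalized offline)
fallgan score --checkpoint runs/desk/checkpoint_final.npz \
              --clip data/test/test_fall_000 --stride 1 --mode offline \
              --out scores/test_fall_000.csv

# pool score CSVs into frame-level AUC / score-gap / confusion report
fallgan eval --scores scores/ --mode offline --threshold 0.3 --out report/

# everything in one reproducible run
fallgan demo --out demo_run/ --seed 1
```

Every command accepts `--config config.yaml`, `--preset desk|paper` and
dot-path overrides such as `--set train.max_iterations=100`. The `desk`
preset (64×64 frames, tiny nets, 450 iterations) is the CPU-scale
default; the `paper` preset carries the full-scale settings (256×256,
70-px discriminator patches, batch 7, lr 1e-4 decaying ×0.1 every
70 000 iterations). The resolved config is echoed into every output
directory.

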