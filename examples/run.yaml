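# Desk-scale run configuration: train a depth-3 model on a phantom split.
# Generate the data first, e.g.:
#   pdcnet synth --out phantoms --n-train 12 --n-val 4 --n-test 4 --seed 1
model:
  depth: 3
  base_channels: 8
  variant: pdcm_previous   # no_pdcm | pdcm_no_previous | pdcm_previous
  use_residual: true
  seed: 3
data:
  root: phantoms
train:
  batch_size: 4
  epochs: 60
  learning_rate: 1.0e-3
  seed: 4
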