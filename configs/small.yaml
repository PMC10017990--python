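# Desk-scale configuration: small encoder profile and shortened training
# recipes suitable for a single CPU.  Drives the whole pipeline:
#
#   cropformer simulate --config configs/small.yaml --out-dir runs/data
#   cropformer pretrain --unlabeled runs/data/unlabeled.csv \
#       --config configs/small.yaml --out runs/encoder.npz
#   cropformer finetune --train runs/data/train.csv --val runs/data/val.csv \
#       --pretrained runs/encoder.npz --config configs/small.yaml \
#       --out runs/classifier.npz
#   cropformer evaluate --classifier runs/classifier.npz \
#       --test runs/data/test.csv --out runs/metrics.json

master_seed: 0

model:
  profile: small          # d_spec 16 + d_time 16, 1 block, 4 heads, FFN 64

simulate:
  preset: four_class      # balanced benchmark: 250 labeled per class
  n_unlabeled: 2000

pretrain:                 # desk-scale recipe (see docs/methods.md)
  epochs: 60
  batch_size: 64
  learning_rate: 3.0e-3
  lr_decay_epoch: 15
  lr_decay_factor: 0.85

finetune:
  epochs: 30
  batch_size: 32
  learning_rate: 1.0e-3
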