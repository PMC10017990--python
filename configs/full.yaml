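# Full-size configuration: the complete 256-dimensional encoder and the
# long training recipes.  Provided for completeness; expect hours of CPU
# time — use configs/small.yaml for interactive work.

master_seed: 0

model:
  profile: full           # d_spec 128 + d_time 128, 3 blocks, 8 heads, FFN 1024

simulate:
  preset: four_class
  n_unlabeled: 2000

pretrain:
  epochs: 200
  batch_size: 512
  learning_rate: 1.0e-4
  lr_decay_epoch: 10
  lr_decay_factor: 0.9

finetune:
  epochs: 10
  batch_size: 256
  learning_rate: 1.0e-5
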