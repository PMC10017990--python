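# In-season scenario example: classify using only observations up to the
# end of June (day 181) and the end of August (day 243), three repeats.
# Point the paths at the tables written by `cropformer simulate`.
#
#   cropformer scenario --type in_season \
#       --config configs/scenario_in_season.yaml --out runs/in_season.json

master_seed: 0

model:
  profile: small

finetune:
  epochs: 30
  batch_size: 32
  learning_rate: 1.0e-3

paths:
  train: runs/data/train.csv
  val: runs/data/val.csv
  test: runs/data/test.csv

scenario:
  n_repeats: 3
  cutoffs: [181, 243]
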