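# 8-tip toy analysis: exercises every pipeline stage in seconds.
seed: 1
tree: tree.nwk
occurrences: occurrences.tsv
stage_models: [ER, SYM, ARD, stage]
class_models: [ER]
n_restarts: 3
out_dir: out
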