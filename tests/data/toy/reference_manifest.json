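{
  "inputs": {
    "occurrences": "4216895d804152293599ce68647300777a6536f95178d563f6b60eac6d9696dd",
    "tree": "a6cb2aac683e37956c29642c6e6f98d3357146b2a674f7a335d77c9858e7293d"
  },
  "outputs": {
    "character_class.tsv": "080235cc8dd3467787f34978aaa649e4d437b842f327bdac59273102ef39a48f",
    "character_complexity.tsv": "ff476e2722578b1ab2244caaa1bf6651ad93821574371ca4064df213fade99f7",
    "character_stage.tsv": "e152c5899ab29a46c26e4701ec3b9e6b4393db1900b34c8d50dc98bf7255e16c",
    "class_asr.nex": "6934c22c87be4765d57db236e9e2ed573640543b1a37d02c3eff28bf615c5f3d",
    "class_asr.tsv": "155930698d27fc956b6de000e3199125cdd2e706b097530ced5f9f558a422b7e",
    "class_model_fits.tsv": "ed757120d5dff575139b9d8e064bed49c15086cc7333056cd690ca8287c3047c",
    "complexity_asr.tsv": "a7fbc6f787e8c55d8a5ddc97285423a8659465861b5db806bb28f11c21f6bdcf",
    "complexity_painting.tsv": "50267ce08ace46a37481ced7ff9ba8d785996d1c80ab5d4192ee147442a1efcf",
    "stage_asr.nex": "645c776020268c1933305b66d736c7da8609ef32a9e2697ed444fb5397e54022",
    "stage_asr.tsv": "b18e1d2d870d6e928da72337376f64bedc8a097f4810c3f3da37bf6b216089df",
    "stage_lrt.tsv": "3297e40cda66a0d2cf709d37382f030c187452f4ff79b44cb1661cab13636c3a",
    "stage_model_fits.tsv": "15b9276d666e4906938dbc682ac462e2f07c51c424976bcf619c9f9aa1523edd",
    "summary.txt": "fc5ade7d28d3d9183ca733cc7b5d864d3be55a1d89c35314cf019f8f40859c2e"
  },
  "parameters": {
    "alpha": 0.05,
    "class_models": [
      "ER"
    ],
    "class_policy": "polymorphic",
    "n_restarts": 3,
    "occurrences": "occurrences.tsv",
    "root": "fitzjohn",
    "seed": 1,
    "stage_models": [
      "ER",
      "SYM",
      "ARD",
      "stage"
    ],
    "threshold": 0.75,
    "tree": "tree.nwk"
  },
  "seed": 1,
  "version": "0.1.0"
}
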