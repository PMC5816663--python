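# Transcription of the C1 fossil calibration scheme for millipede
# divergence dating (node priors as printed in the source record).
scheme = C1

[calibration]
clade = Chilopoda
distribution = lognormal
offset = 383.0
mu = 2.0
sigma = 0.5
note = based on the fossil Devonobius delta

[calibration]
clade = Diplopoda
distribution = uniform
lower = 423.0
upper = 580.0
note = lower bound from Pneumodesmus newmani deposits; upper bound from oldest Ediacaran fossils

[calibration]
clade = Glomerida+Glomeridesmida
distribution = lognormal_real_space
mean = 33.9
sigma = 2.0
note = based on the fossil Glomeris denticulata

[calibration]
clade = Julida
distribution = lognormal_real_space
mean = 33.9
sigma = 1.0
note = based on the fossil Parajulus cockerelli

[calibration]
clade = Nematophora
distribution = uniform
lower = 307.0
upper = 580.0
note = lower bound from the deposit of the oldest Hexecontasoma fossil

[calibration]
clade = Pyrgodesmidae
distribution = lognormal_real_space
mean = 13.65
sigma = 1.0
note = based on the fossil Psochodesmus crescentis; sd not stated in the source record, 1.0 is an editable placeholder
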