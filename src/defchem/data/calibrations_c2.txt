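# Transcription of the C2 fossil calibration scheme: prior spreads derived
# from Penultimate Gap (PenG) and ghost lineage length (GLin) statistics by
# an unpublished procedure; only the resulting parameters were printed, so
# only those are transcribed.  The underlying fossil ages were not printed.
scheme = C2

[calibration]
clade = Chilopoda
distribution = lognormal
offset = 417.0
mu = 1.74
sigma = 1.81
note = crown-group Chilopoda; sd printed with a comma decimal (1,81), transcribed as 1.81

[calibration]
clade = Helminthomorpha+Pentazonia
distribution = lognormal
offset = 423.0
mu = 1.2
sigma = 1.81
note = stem Helminthomorpha
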