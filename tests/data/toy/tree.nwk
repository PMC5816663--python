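((((F1:20,F2:20):30,F3:50):25,(F4:40,F5:40):35):25,((F6:30,F7:30):30,F8:60):40);
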