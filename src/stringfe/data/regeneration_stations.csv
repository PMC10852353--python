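label,kind,free_energy
P,minimum,0.0
TS7,saddle,5.2
Q,minimum,-11.23
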