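label,kind,free_energy
ACE,minimum,0.0
TS5,saddle,18.6
I4,minimum,12.7
TS6,saddle,20.9
P,minimum,5.8
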