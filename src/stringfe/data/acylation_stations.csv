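label,kind,free_energy
R,minimum,1.4
TS1,saddle,14.0
I1,minimum,11.2
TS2,saddle,18.6
I2,minimum,11.7
TS3,saddle,13.7
I3,minimum,11.7
TS4,saddle,13.6
ACE+NH3,minimum,2.7
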