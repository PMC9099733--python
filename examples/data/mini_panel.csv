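locus_id,chromosome,position_bp,change,rep_avg,call_rate,CultivarA,CultivarB,CultivarC
L000001,1H,1250000,A>G,0.99,1.0,1,0,1
L000001,1H,1250000,A>G,0.99,1.0,0,1,1
L000002,5H,88000000,C>T,0.97,1.0,1,1,0
L000002,5H,88000000,C>T,0.97,1.0,0,1,0
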