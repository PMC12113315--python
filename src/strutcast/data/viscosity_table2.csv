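T_C,PCL,PCL_D10,PCL_D20,PCL_D30
120,1286.6,863.0,696.9,333.8
125,1094.4,816.3,662.1,316.6
130,1018.9,762.7,622.2,286.5
135,946.0,749.7,577.1,251.1
140,889.5,720.1,526.9,229.1
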