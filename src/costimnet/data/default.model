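# costimnet multistate logic model
species: I Ox Tr1 Tr2 Tr5 Nk PKB ERK JNK Bim S C
inputs: I Ox

[Tr1]
parents: I
0 -> 0
1 -> 1
2 -> 2

[Tr2]
parents: I Ox Tr1
0 0 0 -> 0
0 0 1 -> 0
0 0 2 -> 1
0 1 0 -> 0
0 1 1 -> 0
0 1 2 -> 1
0 2 0 -> 0
0 2 1 -> 1
0 2 2 -> 2
1 0 0 -> 0
1 0 1 -> 1
1 0 2 -> 2
1 1 0 -> 0
1 1 1 -> 1
1 1 2 -> 2
1 2 0 -> 1
1 2 1 -> 2
1 2 2 -> 2
2 0 0 -> 1
2 0 1 -> 2
2 0 2 -> 2
2 1 0 -> 1
2 1 1 -> 2
2 1 2 -> 2
2 2 0 -> 1
2 2 1 -> 2
2 2 2 -> 2

[Tr5]
parents: Ox
0 -> 0
1 -> 1
2 -> 2

[Nk]
parents: Tr2 Tr5
0 0 -> 0
0 1 -> 0
0 2 -> 1
1 0 -> 1
1 1 -> 1
1 2 -> 1
2 0 -> 1
2 1 -> 2
2 2 -> 2

[PKB]
parents: Tr2 Ox
0 0 -> 0
0 1 -> 0
0 2 -> 1
1 0 -> 0
1 1 -> 1
1 2 -> 1
2 0 -> 1
2 1 -> 1
2 2 -> 2

[ERK]
parents: Tr1
0 -> 0
1 -> 1
2 -> 2

[JNK]
parents: Tr2 Nk
0 0 -> 1
0 1 -> 0
0 2 -> 0
1 0 -> 2
1 1 -> 1
1 2 -> 0
2 0 -> 2
2 1 -> 2
2 2 -> 1

[Bim]
parents: JNK ERK PKB
0 0 0 -> 1
0 0 1 -> 0
0 0 2 -> 0
0 1 0 -> 0
0 1 1 -> 0
0 1 2 -> 0
0 2 0 -> 0
0 2 1 -> 0
0 2 2 -> 0
1 0 0 -> 2
1 0 1 -> 1
1 0 2 -> 0
1 1 0 -> 1
1 1 1 -> 1
1 1 2 -> 0
1 2 0 -> 0
1 2 1 -> 0
1 2 2 -> 0
2 0 0 -> 2
2 0 1 -> 2
2 0 2 -> 1
2 1 0 -> 2
2 1 1 -> 2
2 1 2 -> 1
2 2 0 -> 1
2 2 1 -> 1
2 2 2 -> 1

[S]
parents: Nk PKB Bim JNK
0 0 0 0 -> 0
0 0 0 1 -> 0
0 0 0 2 -> 0
0 0 1 0 -> 0
0 0 1 1 -> 0
0 0 1 2 -> 0
0 0 2 0 -> 0
0 0 2 1 -> 0
0 0 2 2 -> 0
0 1 0 0 -> 0
0 1 0 1 -> 0
0 1 0 2 -> 0
0 1 1 0 -> 0
0 1 1 1 -> 0
0 1 1 2 -> 0
0 1 2 0 -> 0
0 1 2 1 -> 0
0 1 2 2 -> 0
0 2 0 0 -> 2
0 2 0 1 -> 2
0 2 0 2 -> 2
0 2 1 0 -> 2
0 2 1 1 -> 2
0 2 1 2 -> 1
0 2 2 0 -> 2
0 2 2 1 -> 1
0 2 2 2 -> 0
1 0 0 0 -> 0
1 0 0 1 -> 0
1 0 0 2 -> 0
1 0 1 0 -> 0
1 0 1 1 -> 0
1 0 1 2 -> 0
1 0 2 0 -> 0
1 0 2 1 -> 0
1 0 2 2 -> 0
1 1 0 0 -> 1
1 1 0 1 -> 1
1 1 0 2 -> 1
1 1 1 0 -> 1
1 1 1 1 -> 1
1 1 1 2 -> 1
1 1 2 0 -> 1
1 1 2 1 -> 1
1 1 2 2 -> 0
1 2 0 0 -> 2
1 2 0 1 -> 2
1 2 0 2 -> 2
1 2 1 0 -> 2
1 2 1 1 -> 2
1 2 1 2 -> 2
1 2 2 0 -> 2
1 2 2 1 -> 2
1 2 2 2 -> 1
2 0 0 0 -> 2
2 0 0 1 -> 2
2 0 0 2 -> 2
2 0 1 0 -> 2
2 0 1 1 -> 2
2 0 1 2 -> 1
2 0 2 0 -> 2
2 0 2 1 -> 1
2 0 2 2 -> 0
2 1 0 0 -> 2
2 1 0 1 -> 2
2 1 0 2 -> 2
2 1 1 0 -> 2
2 1 1 1 -> 2
2 1 1 2 -> 2
2 1 2 0 -> 2
2 1 2 1 -> 2
2 1 2 2 -> 1
2 2 0 0 -> 2
2 2 0 1 -> 2
2 2 0 2 -> 2
2 2 1 0 -> 2
2 2 1 1 -> 2
2 2 1 2 -> 2
2 2 2 0 -> 2
2 2 2 1 -> 2
2 2 2 2 -> 2

[C]
parents: Nk JNK
0 0 -> 0
0 1 -> 0
0 2 -> 1
1 0 -> 1
1 1 -> 1
1 2 -> 1
2 0 -> 2
2 1 -> 2
2 2 -> 2
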