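age,female,male
15,21,18
16,18,23
17,20,21
18,22,20
19,21,20
20,20,17
21,20,20
22,18,15
23,24,21
24,16,14
25,20,14
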