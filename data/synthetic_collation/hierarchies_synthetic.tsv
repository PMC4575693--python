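area	hierarchy	level
A01	synthetic	9
A08	synthetic	9
A11	synthetic	10
A12	synthetic	9
A13	synthetic	8
A15	synthetic	6
A19	synthetic	9
A22	synthetic	5
A24	synthetic	8
A25	synthetic	9
A26	synthetic	6
A28	synthetic	9
A31	synthetic	9
A34	synthetic	9
A47	synthetic	9
A48	synthetic	5
A49	synthetic	9
A50	synthetic	7
A52	synthetic	7
A57	synthetic	1
A59	synthetic	1
A61	synthetic	9
A64	synthetic	3
A01	synthetic-alt	8
A08	synthetic-alt	9
A11	synthetic-alt	9
A12	synthetic-alt	8
A13	synthetic-alt	7
A15	synthetic-alt	7
A19	synthetic-alt	9
A22	synthetic-alt	6
A24	synthetic-alt	5
A25	synthetic-alt	9
A26	synthetic-alt	4
A28	synthetic-alt	9
A31	synthetic-alt	10
A34	synthetic-alt	10
A47	synthetic-alt	9
A48	synthetic-alt	5
A49	synthetic-alt	8
A50	synthetic-alt	7
A52	synthetic-alt	7
A57	synthetic-alt	1
A59	synthetic-alt	1
A61	synthetic-alt	9
A64	synthetic-alt	2
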