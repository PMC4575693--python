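area	structural_type	module	hub
A00	3.0	fronto-limbic	0
A01	1.0	auditory	0
A02		auditory	0
A03		visual	0
A04		auditory	0
A05	2.0	visual	0
A06	3.0	fronto-limbic	0
A07	1.0	somatosensory-motor	0
A08	1.0	auditory	0
A09	2.0	somatosensory-motor	0
A10	1.0	somatosensory-motor	1
A11	1.0	auditory	1
A12	1.0	auditory	0
A13	2.0	auditory	0
A14		visual	0
A15	2.0	auditory	0
A16	4.0	somatosensory-motor	0
A17		fronto-limbic	0
A18	3.0	fronto-limbic	1
A19	1.0	auditory	0
A20	1.0	visual	0
A21	4.0	fronto-limbic	0
A22	3.0	auditory	0
A23	2.0	visual	1
A24	2.0	auditory	1
A25	1.0	auditory	0
A26	3.0	auditory	0
A27		somatosensory-motor	0
A28	1.0	auditory	1
A29		auditory	0
A30		auditory	0
A31	1.0	auditory	0
A32	1.0	somatosensory-motor	0
A33	3.0	visual	0
A34	1.0	auditory	1
A35	5.0	fronto-limbic	0
A36	1.0	visual	0
A37		somatosensory-motor	0
A38	1.0	somatosensory-motor	0
A39		visual	0
A40	2.0	visual	1
A41	2.0	somatosensory-motor	0
A42	1.0	visual	0
A43	1.0	visual	0
A44		somatosensory-motor	0
A45		visual	0
A46	4.0	fronto-limbic	0
A47	1.0	auditory	1
A48	3.0	auditory	0
A49	1.0	auditory	1
A50	2.0	auditory	0
A51		fronto-limbic	0
A52	2.0	auditory	1
A53	1.0	visual	0
A54	4.0	fronto-limbic	0
A55	4.0	fronto-limbic	0
A56		visual	0
A57	5.0	auditory	0
A58	2.0	visual	0
A59	5.0	auditory	0
A60		fronto-limbic	0
A61	1.0	auditory	0
A62	3.0	fronto-limbic	0
A63		fronto-limbic	0
A64	5.0	auditory	0
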