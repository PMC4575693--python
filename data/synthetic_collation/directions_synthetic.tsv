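source	target	direction	reliable
A01	A08	L	1
A01	A11	A	1
A01	A12	D	1
A01	A19	L	0
A01	A22	D	0
A01	A24	D	1
A01	A25	L	0
A01	A26	D	1
A01	A28	L	1
A01	A31	L	1
A01	A34	L	1
A01	A47	A	1
A01	A48	D	0
A01	A49	L	0
A01	A50	D	1
A01	A52	D	1
A01	A61	L	0
A01	A64	D	1
A08	A01	L	0
A08	A11	A	1
A08	A12	L	0
A08	A13	D	1
A08	A15	D	1
A08	A19	L	1
A08	A22	D	0
A08	A24	D	1
A08	A25	L	1
A08	A26	D	1
A08	A28	L	1
A08	A31	L	1
A08	A34	L	0
A08	A47	L	0
A08	A48	D	1
A08	A49	L	1
A08	A50	D	1
A08	A52	D	1
A08	A59	D	1
A08	A61	L	1
A11	A12	D	1
A11	A13	D	1
A11	A15	D	1
A11	A19	D	1
A11	A22	D	1
A11	A24	D	1
A11	A25	D	1
A11	A28	D	1
A11	A31	D	1
A11	A34	D	1
A11	A47	D	1
A11	A49	D	1
A11	A50	D	1
A11	A52	D	1
A11	A61	D	1
A12	A01	L	1
A12	A08	L	1
A12	A11	A	1
A12	A13	A	1
A12	A15	D	1
A12	A19	L	0
A12	A24	D	1
A12	A25	L	0
A12	A26	D	1
A12	A31	L	0
A12	A34	L	1
A12	A47	L	1
A12	A48	D	1
A12	A49	L	1
A12	A50	D	1
A12	A52	D	1
A12	A57	D	1
A13	A01	A	1
A13	A08	A	1
A13	A11	A	1
A13	A12	A	0
A13	A15	D	1
A13	A19	A	1
A13	A22	D	1
A13	A24	L	1
A13	A25	A	1
A13	A26	D	1
A13	A28	A	1
A13	A31	A	0
A13	A34	A	1
A13	A48	D	0
A13	A49	A	0
A13	A50	D	1
A13	A52	D	1
A13	A59	D	1
A13	A61	D	1
A13	A64	D	1
A15	A01	A	1
A15	A08	A	0
A15	A11	A	1
A15	A13	A	0
A15	A19	A	1
A15	A22	D	1
A15	A24	A	1
A15	A25	A	1
A15	A26	D	1
A15	A28	A	1
A15	A31	A	1
A15	A34	A	1
A15	A47	A	1
A15	A48	L	1
A15	A50	A	1
A15	A52	A	1
A15	A57	D	1
A15	A61	A	1
A15	A64	D	0
A19	A01	L	1
A19	A08	L	1
A19	A11	A	1
A19	A12	L	1
A19	A13	D	0
A19	A15	D	1
A19	A22	D	1
A19	A24	D	0
A19	A25	L	1
A19	A26	L	1
A19	A28	L	1
A19	A31	L	1
A19	A34	D	1
A19	A47	L	0
A19	A48	D	0
A19	A50	D	1
A19	A52	D	1
A19	A61	L	1
A22	A01	A	1
A22	A08	A	0
A22	A11	A	1
A22	A15	A	1
A22	A24	A	1
A22	A25	A	1
A22	A26	A	1
A22	A28	D	1
A22	A31	A	1
A22	A34	A	0
A22	A48	D	1
A22	A50	A	1
A22	A52	A	1
A22	A57	D	1
A22	A59	D	0
A22	A61	A	1
A22	A64	D	1
A24	A01	A	1
A24	A11	A	1
A24	A12	A	1
A24	A13	L	1
A24	A15	D	1
A24	A22	D	0
A24	A25	A	1
A24	A26	D	1
A24	A28	A	0
A24	A31	A	1
A24	A34	A	1
A24	A47	A	1
A24	A48	A	1
A24	A49	A	0
A24	A50	D	0
A24	A52	D	1
A24	A57	D	1
A24	A61	A	0
A24	A64	D	1
A25	A01	L	1
A25	A08	L	1
A25	A11	A	0
A25	A12	L	1
A25	A13	D	1
A25	A15	D	1
A25	A19	L	1
A25	A22	D	1
A25	A24	D	1
A25	A26	D	1
A25	A28	L	1
A25	A31	D	1
A25	A34	L	1
A25	A47	L	1
A25	A48	D	1
A25	A49	L	1
A25	A50	D	1
A25	A52	D	1
A25	A57	D	1
A25	A59	D	1
A25	A61	L	1
A26	A01	A	1
A26	A08	A	1
A26	A12	A	0
A26	A13	A	1
A26	A15	L	0
A26	A19	A	1
A26	A22	D	0
A26	A24	A	1
A26	A25	A	1
A26	A28	A	1
A26	A34	A	0
A26	A47	A	1
A26	A48	D	0
A26	A49	A	1
A26	A50	A	1
A26	A52	A	1
A26	A57	D	1
A26	A64	D	1
A28	A01	L	1
A28	A08	L	1
A28	A11	A	1
A28	A12	D	1
A28	A15	A	1
A28	A19	L	1
A28	A22	A	0
A28	A24	D	0
A28	A25	L	1
A28	A31	A	1
A28	A34	L	1
A28	A47	L	1
A28	A48	D	1
A28	A49	L	1
A28	A50	D	1
A28	A52	D	1
A28	A57	D	1
A28	A59	D	1
A28	A61	L	1
A31	A01	L	1
A31	A08	L	1
A31	A11	A	0
A31	A12	L	1
A31	A13	D	1
A31	A15	D	1
A31	A19	L	1
A31	A24	D	1
A31	A25	L	0
A31	A26	A	0
A31	A28	D	0
A31	A34	L	1
A31	A47	L	1
A31	A48	D	1
A31	A49	L	1
A31	A50	D	1
A31	A61	L	1
A34	A01	L	1
A34	A08	L	1
A34	A12	L	1
A34	A13	D	1
A34	A15	D	1
A34	A19	L	1
A34	A22	D	1
A34	A24	D	1
A34	A25	L	1
A34	A26	L	1
A34	A28	L	0
A34	A31	L	1
A34	A47	L	1
A34	A48	D	0
A34	A49	L	0
A34	A50	D	1
A34	A52	D	1
A34	A61	A	0
A34	A64	D	1
A47	A01	L	1
A47	A08	L	1
A47	A11	A	0
A47	A12	L	0
A47	A13	D	0
A47	A15	D	1
A47	A19	L	1
A47	A22	D	1
A47	A24	D	1
A47	A25	L	0
A47	A26	D	0
A47	A28	L	1
A47	A31	L	1
A47	A34	L	0
A47	A48	D	1
A47	A49	L	1
A47	A50	D	1
A47	A52	D	1
A47	A57	D	0
A47	A59	L	0
A48	A01	A	1
A48	A11	A	0
A48	A12	A	1
A48	A15	A	0
A48	A22	L	1
A48	A24	A	1
A48	A25	A	1
A48	A26	A	1
A48	A28	A	1
A48	A34	A	0
A48	A47	A	1
A48	A49	A	1
A48	A50	A	1
A48	A57	D	1
A48	A59	D	1
A48	A61	A	1
A48	A64	D	1
A49	A01	L	1
A49	A08	D	0
A49	A11	A	1
A49	A12	L	1
A49	A13	D	1
A49	A19	A	1
A49	A22	D	0
A49	A24	D	1
A49	A25	L	1
A49	A26	D	1
A49	A28	L	1
A49	A31	L	1
A49	A34	L	1
A49	A47	L	0
A49	A48	D	1
A49	A50	L	1
A49	A52	A	1
A49	A61	L	0
A50	A01	A	1
A50	A08	A	1
A50	A11	D	1
A50	A12	A	1
A50	A13	A	1
A50	A15	D	1
A50	A19	A	1
A50	A22	D	0
A50	A24	A	1
A50	A25	A	0
A50	A26	L	1
A50	A28	A	1
A50	A31	A	1
A50	A34	A	1
A50	A47	A	1
A50	A48	D	1
A50	A49	A	0
A50	A52	L	1
A50	A57	D	1
A50	A59	D	1
A50	A61	A	1
A50	A64	D	1
A52	A01	L	1
A52	A08	A	0
A52	A11	A	0
A52	A12	A	0
A52	A13	A	0
A52	A15	D	1
A52	A19	A	1
A52	A22	D	1
A52	A24	A	1
A52	A25	A	0
A52	A26	D	1
A52	A28	A	1
A52	A31	D	0
A52	A34	A	1
A52	A47	A	1
A52	A48	D	1
A52	A49	A	1
A52	A50	L	1
A52	A57	D	1
A52	A59	D	1
A52	A61	A	1
A52	A64	D	1
A57	A11	A	1
A57	A13	A	0
A57	A19	L	1
A57	A22	D	1
A57	A26	A	1
A57	A31	A	1
A57	A47	A	0
A57	A50	A	0
A57	A52	A	1
A57	A59	L	0
A57	A61	L	1
A57	A64	A	1
A59	A08	A	1
A59	A15	A	1
A59	A22	A	1
A59	A24	A	1
A59	A26	A	1
A59	A47	A	0
A59	A48	A	1
A59	A50	A	1
A59	A52	A	1
A59	A57	L	1
A59	A64	A	1
A61	A01	L	1
A61	A08	L	1
A61	A11	A	1
A61	A12	L	1
A61	A15	D	1
A61	A19	L	1
A61	A22	A	1
A61	A24	D	0
A61	A25	L	1
A61	A26	D	1
A61	A28	L	0
A61	A31	L	1
A61	A34	L	1
A61	A47	L	1
A61	A49	A	1
A61	A50	D	1
A61	A52	D	1
A61	A59	L	0
A64	A08	A	1
A64	A19	A	0
A64	A22	A	0
A64	A24	A	1
A64	A26	A	1
A64	A34	A	1
A64	A50	A	1
A64	A52	A	1
A64	A57	D	1
A64	A59	D	0
A64	A61	A	1
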