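	a	b	c	d	e	f	g	h	i	j	k	l	m	n	o	p
a	2.00	-2.07	-1.20	-1.66	-2.57	-2.25	-1.84	-2.91	-2.52	-2.71	-2.99	-2.35	-2.61	-3.02	-2.55	-2.11
b	-2.07	2.00	-1.09	-0.61	-1.79	-1.80	-2.14	-2.06	-0.81	-2.04	-0.94	-1.79	-2.55	-3.02	-2.53	-1.79
c	-1.20	-1.09	2.00	-0.49	-1.68	-1.33	-1.24	-2.17	-2.13	-2.00	-2.30	-2.84	-2.56	-2.94	-2.33	-1.50
d	-1.66	-0.61	-0.49	2.00	-0.86	-0.72	-2.19	-1.62	-1.45	-1.39	-1.90	-2.67	-3.70	-4.00	-3.38	-2.74
e	-2.57	-1.79	-1.68	-0.86	2.00	-1.57	-1.09	-2.22	-2.43	-2.19	-2.27	-3.00	-3.91	-3.08	-3.91	-3.32
f	-2.25	-1.80	-1.33	-0.72	-1.57	2.00	-2.69	-0.45	-2.40	-1.14	-0.75	-1.79	-2.66	-3.27	-2.88	-3.01
g	-1.84	-2.14	-1.24	-2.19	-1.09	-2.69	2.00	-3.04	-2.96	-3.31	-2.89	-2.51	-2.24	-0.97	-2.26	-1.93
h	-2.91	-2.06	-2.17	-1.62	-2.22	-0.45	-3.04	2.00	-2.64	-1.75	-1.35	-2.28	-3.04	-3.70	-2.10	-3.27
i	-2.52	-0.81	-2.13	-1.45	-2.43	-2.40	-2.96	-2.64	2.00	-1.31	-1.55	-2.27	-3.22	-3.58	-3.51	-1.15
j	-2.71	-2.04	-2.00	-1.39	-2.19	-1.14	-3.31	-1.75	-1.31	2.00	-1.08	-2.10	-2.71	-3.30	-3.62	-2.35
k	-2.99	-0.94	-2.30	-1.90	-2.27	-0.75	-2.89	-1.35	-1.55	-1.08	2.00	-0.81	-1.78	-2.45	-2.52	-2.52
l	-2.35	-1.79	-2.84	-2.67	-3.00	-1.79	-2.51	-2.28	-2.27	-2.10	-0.81	2.00	-0.83	-1.63	-1.80	-2.25
m	-2.61	-2.55	-2.56	-3.70	-3.91	-2.66	-2.24	-3.04	-3.22	-2.71	-1.78	-0.83	2.00	-0.41	-0.65	-1.57
n	-3.02	-3.02	-2.94	-4.00	-3.08	-3.27	-0.97	-3.70	-3.58	-3.30	-2.45	-1.63	-0.41	2.00	-1.84	-2.09
o	-2.55	-2.53	-2.33	-3.38	-3.91	-2.88	-2.26	-2.10	-3.51	-3.62	-2.52	-1.80	-0.65	-1.84	2.00	-1.96
p	-2.11	-1.79	-1.50	-2.74	-3.32	-3.01	-1.93	-3.27	-1.15	-2.35	-2.52	-2.25	-1.57	-2.09	-1.96	2.00
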