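# Per-linkage-group map summary of the spruce bark beetle linkage map
# (male, female and sex-averaged maps reconstructed from two families).
# LG16 is the X chromosome; the male map has no X rows because the X is
# hemizygous in males. Lengths in centimorgan, physical sizes in megabases.
lg	male_cM	male_markers	female_cM	female_markers	sexavg_cM	sexavg_markers	length_Mb
1	115.65	76527	97.68	69705	106.66	88081	31.12
2	99.33	61538	102.73	51305	101.02	68683	26.55
3	83.69	43396	79.60	34497	81.64	48256	22.52
4	51.70	42290	53.06	34587	52.38	47054	14.41
5	78.92	31249	68.03	27964	73.47	36991	14.45
6	54.43	31239	48.31	21752	51.36	32153	12.14
7	49.66	29787	54.43	12439	52.04	31548	9.59
8	51.71	24911	54.43	19924	53.06	27783	8.70
9	42.86	25153	47.63	20786	45.24	25960	9.86
10	51.71	11370	55.83	22135	53.75	24595	8.07
11	99.83	12940	59.90	9503	81.10	15728	11.01
12	52.39	9642	49.68	5519	51.02	10256	10.60
13	75.81	4161	61.23	3780	67.38	5233	7.77
14	52.45	2693	65.40	2374	58.86	3024	7.08
15	44.23	1641	56.36	1426	48.65	1809	9.53
16	NA	NA	63.35	124	63.35	124	9.65
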