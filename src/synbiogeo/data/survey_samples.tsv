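sample	spring	basin	barcode	collection_date	n_genotypes	n_sequences	excluded
Mushroom Spring A	Mushroom Spring	Lower Geyser Basin	64	1996-05-31	774	2063	0
Mushroom Spring B	Mushroom Spring	Lower Geyser Basin	82	1996-05-31	756	1696	0
Octopus Spring Low A	Octopus Spring Low	Lower Geyser Basin	73	1996-05-31	57	69	1
Octopus Spring Low B	Octopus Spring Low	Lower Geyser Basin	74	1996-05-31	830	2018	1
Octopus Spring Med	Octopus Spring Med	Lower Geyser Basin	65	1996-05-31	793	1906	0
Octopus Spring High	Octopus Spring High	Lower Geyser Basin	72	1996-05-31	489	2262	1
Twin Butte Vista A	Twin Butte Vista	Lower Geyser Basin	77	1996-05-31	711	1954	0
Twin Butte Vista B	Twin Butte Vista	Lower Geyser Basin	78	1996-05-31	537	2022	0
Clearwater East A	Clearwater East	Clearwater Springs	91	1996-05-30	391	3208	1
Clearwater East B	Clearwater East	Clearwater Springs	92	1996-05-30	389	4136	1
Clearwater South	Clearwater South	Clearwater Springs	93	1996-05-30	550	1286	0
Heart Pool A	Heart Pool	West Thumb	75	1996-05-31	549	1678	0
Heart Pool B	Heart Pool	West Thumb	76	1996-05-31	590	1866	0
Mantrap Spring A	Mantrap Spring	West Thumb	85	1996-05-31	637	1562	0
Mantrap Spring B	Mantrap Spring	West Thumb	86	1996-05-31	58	86	1
Bath Lake Vista	Bath Lake Vista	Mammoth Hot Springs	62	1996-05-30	280	4904	0
New Mound A	New Mound	Mammoth Hot Springs	89	1996-05-30	228	4526	0
New Mound B	New Mound	Mammoth Hot Springs	90	1996-05-30	278	4703	0
White Elephant Back A	White Elephant Back	Mammoth Hot Springs	81	1996-05-30	288	4621	0
White Elephant Back B	White Elephant Back	Mammoth Hot Springs	84	1996-05-30	317	4710	0
LaDuke Spring	LaDuke Spring	LaDuke	80	1996-05-30	503	1426	0
Bozeman Spring	Bozeman Spring	Bozeman	83	1996-07-08	319	3932	0
Jack's Spring Low A	Jack's Spring Low	Oregon Springs	71	1996-07-07	276	1827	0
Jack's Spring Low B	Jack's Spring Low	Oregon Springs	87	1996-07-07	260	1782	0
Jack's Spring High	Jack's Spring High	Oregon Springs	63	1996-07-07	228	2101	1
Levee Spring A	Levee Spring	Oregon Springs	69	1996-07-07	381	2287	0
Levee Spring B	Levee Spring	Oregon Springs	70	1996-07-07	376	2254	0
Perpetual Spring	Perpetual Spring	Oregon Springs	67	1996-07-07	383	2014	0
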