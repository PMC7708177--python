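table	mirna_id	hybrid	da	category
common	zma-miR160b-3p	Zhengdan 958	8.36	++
common	zma-miR160b-3p	Anyu 5	2.69	++
common	zma-miR160b-3p	Zheng 58 x Huangzaosi	3.26	++
common	zma-miR160b-3p	Ye 478 x Huangzaosi	2.62	++
common	zma-miR166b-5p	Zhengdan 958	5.38	++
common	zma-miR166b-5p	Anyu 5	-0.6	-
common	zma-miR166b-5p	Zheng 58 x Huangzaosi	12.99	++
common	zma-miR166b-5p	Ye 478 x Huangzaosi	0.34	+-
common	zma-miR171g-5p	Zhengdan 958	18.79	++
common	zma-miR171g-5p	Anyu 5	58.05	++
common	zma-miR171g-5p	Zheng 58 x Huangzaosi	10.14	++
common	zma-miR171g-5p	Ye 478 x Huangzaosi	27.09	++
common	zma-miR169c-3p	Zhengdan 958	1.67	+
common	zma-miR169c-3p	Anyu 5	1.9	+
common	zma-miR169c-3p	Zheng 58 x Huangzaosi	0.9	+
common	zma-miR169c-3p	Ye 478 x Huangzaosi	1.44	+
common	zma-miR399d-5p	Zhengdan 958	1.08	+
common	zma-miR399d-5p	Anyu 5	8.35	++
common	zma-miR399d-5p	Zheng 58 x Huangzaosi	0.41	+-
common	zma-miR399d-5p	Ye 478 x Huangzaosi	2.87	++
common	zma-miR162-3p	Zhengdan 958	-0.11	+-
common	zma-miR162-3p	Anyu 5	-0.22	+-
common	zma-miR162-3p	Zheng 58 x Huangzaosi	-0.2	+-
common	zma-miR162-3p	Ye 478 x Huangzaosi	0.41	+-
common	zma-miR164e-5p	Zhengdan 958	-0.39	+-
common	zma-miR164e-5p	Anyu 5	-0.65	-
common	zma-miR164e-5p	Zheng 58 x Huangzaosi	-0.4	+-
common	zma-miR164e-5p	Ye 478 x Huangzaosi	-0.38	+-
common	zma-miR169f-3p	Zhengdan 958	0.1	+-
common	zma-miR169f-3p	Anyu 5	0.74	+
common	zma-miR169f-3p	Zheng 58 x Huangzaosi	0.33	+-
common	zma-miR169f-3p	Ye 478 x Huangzaosi	0.36	+-
common	zma-miR397b-3p	Zhengdan 958	-0.47	+-
common	zma-miR397b-3p	Anyu 5	-0.21	+-
common	zma-miR397b-3p	Zheng 58 x Huangzaosi	-0.8	-
common	zma-miR397b-3p	Ye 478 x Huangzaosi	0.51	+
common	zma-miR167j-3p	Zhengdan 958	-1.06	-
common	zma-miR167j-3p	Anyu 5	-0.36	+-
common	zma-miR167j-3p	Zheng 58 x Huangzaosi	-0.34	+-
common	zma-miR167j-3p	Ye 478 x Huangzaosi	1.43	+
common	zma-miR162-5p	Zhengdan 958	-0.82	-
common	zma-miR162-5p	Anyu 5	-0.74	-
common	zma-miR162-5p	Zheng 58 x Huangzaosi	-0.82	-
common	zma-miR162-5p	Ye 478 x Huangzaosi	-0.53	-
common	zma-miR395a-5p	Zhengdan 958	-0.57	-
common	zma-miR395a-5p	Anyu 5	-2.14	--
common	zma-miR395a-5p	Zheng 58 x Huangzaosi	2.33	++
common	zma-miR395a-5p	Ye 478 x Huangzaosi	-0.19	+-
common	zma-miR1432-5p	Zhengdan 958	-5.36	--
common	zma-miR1432-5p	Anyu 5	-0.92	-
common	zma-miR1432-5p	Zheng 58 x Huangzaosi	-3.71	--
common	zma-miR1432-5p	Ye 478 x Huangzaosi	-1.14	-
miR156	zma-miR156e-3p	Zheng 58 x Huangzaosi	-5.62	--
miR156	zma-miR156h-3p	Zhengdan 958	-0.86	-
miR156	zma-miR156k-5p	Zhengdan 958	-0.99	-
miR156	zma-miR156d-3p	Zhengdan 958	-6.63	--
miR156	zma-miR156d-3p	Zheng 58 x Huangzaosi	-1.56	-
miR156	zma-miR156l-3p	Zheng 58 x Huangzaosi	-0.75	-
miR156	zma-miR156l-3p	Ye 478 x Huangzaosi	-0.35	+-
miR156	zma-miR156j-3p	Anyu 5	-3.19	--
miR156	zma-miR156j-3p	Zheng 58 x Huangzaosi	-1.61	-
miR156	zma-miR156j-3p	Ye 478 x Huangzaosi	-5.11	--
miR156	zma-miR156a-5p	Zhengdan 958	-1.12	-
miR156	zma-miR156a-5p	Ye 478 x Huangzaosi	0.26	+-
miR395	zma-miR395e-5p	Zhengdan 958	-0.3	+-
miR395	zma-miR395a-5p	Zhengdan 958	-0.57	-
miR395	zma-miR395a-5p	Anyu 5	-2.14	--
miR395	zma-miR395a-5p	Zheng 58 x Huangzaosi	2.33	++
miR395	zma-miR395a-5p	Ye 478 x Huangzaosi	-0.19	+-
miR395	zma-miR395o-5p	Zheng 58 x Huangzaosi	0.18	+-
miR395	zma-miR395o-5p	Ye 478 x Huangzaosi	-0.06	+-
miR395	zma-miR395b-3p	Zhengdan 958	-1.02	-
miR395	zma-miR395b-3p	Anyu 5	-1.41	-
miR395	zma-miR395b-3p	Ye 478 x Huangzaosi	0.69	+
miR408_528	zma-miR408b-5p	Zhengdan 958	-8.08	--
miR408_528	zma-miR408b-5p	Anyu 5	-6.08	--
miR408_528	zma-miR408a	Zhengdan 958	1.38	+
miR408_528	zma-miR528a-5p	Anyu 5	-2.96	--
miR408_528	zma-miR528a-5p	Ye 478 x Huangzaosi	-1.09	-
miR408_528	zma-miR528a-3p	Zhengdan 958	-1.72	-
miR408_528	zma-miR528a-3p	Zheng 58 x Huangzaosi	-0.93	-
miR399	zma-miR399e-3p	Anyu 5	0.08	+-
miR399	zma-miR399c-5p	Ye 478 x Huangzaosi	-0.06	+-
miR399	zma-miR399d-5p	Zhengdan 958	1.08	+
miR399	zma-miR399d-5p	Anyu 5	8.35	++
miR399	zma-miR399d-5p	Zheng 58 x Huangzaosi	0.41	+-
miR399	zma-miR399d-5p	Ye 478 x Huangzaosi	2.87	++
miR399	zma-miR399e-5p	Zhengdan 958	13.25	++
miR399	zma-miR399e-5p	Zheng 58 x Huangzaosi	4.52	++
miR399	zma-miR399d-3p	Anyu 5	0.52	+
miR399	zma-miR399d-3p	Ye 478 x Huangzaosi	-0.33	+-
miR399	zma-miR399a-3p	Anyu 5	1.87	+
miR399	zma-miR399a-3p	Ye 478 x Huangzaosi	-0.39	+-
miR399	zma-miR399b-3p	Anyu 5	1.47	+
miR399	zma-miR399b-3p	Ye 478 x Huangzaosi	-0.78	-
miR399	zma-miR399f-3p	Anyu 5	1.08	+
miR399	zma-miR399f-3p	Ye 478 x Huangzaosi	-0.39	+-
miR399	zma-miR399g-3p	Zhengdan 958	33.41	++
miR399	zma-miR399g-3p	Anyu 5	6.16	++
miR399	zma-miR399a-5p	Zhengdan 958	11.18	++
miR399	zma-miR399a-5p	Anyu 5	5.39	++
miR399	zma-miR399a-5p	Ye 478 x Huangzaosi	2.06	++
miR399	zma-miR399j-5p	Zhengdan 958	5.61	++
miR399	zma-miR399j-5p	Anyu 5	1.62	+
miR399	zma-miR399j-5p	Zheng 58 x Huangzaosi	17.75	++
miR399	zma-miR399i-5p	Anyu 5	-0.91	-
miR399	zma-miR399i-5p	Zheng 58 x Huangzaosi	0.63	+
miR399	zma-miR399i-5p	Ye 478 x Huangzaosi	-0.66	-
miR399	zma-miR399b-5p	Anyu 5	2.37	++
miR399	zma-miR399b-5p	Zheng 58 x Huangzaosi	-1.08	-
miR399	zma-miR399b-5p	Ye 478 x Huangzaosi	-0.72	-
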