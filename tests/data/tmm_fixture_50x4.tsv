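transcript	s1	s2	s3	s4
T000	101	161	64	616
T001	52	75	26	416
T002	33	36	15	160
T003	156	231	117	1280
T004	65	93	43	464
T005	209	322	149	1832
T006	7	11	6	40
T007	140	247	101	1176
T008	136	232	89	1016
T009	36	41	17	280
T010	102	216	115	1184
T011	68	115	43	384
T012	132	174	80	768
T013	60	75	34	496
T014	215	375	159	1752
T015	5	15	8	9
T016	51	83	38	41
T017	55	102	46	67
T018	252	379	191	238
T019	145	247	102	165
T020	133	233	85	154
T021	61	80	36	58
T022	98	172	73	103
T023	59	125	43	73
T024	84	163	74	75
T025	24	42	17	14
T026	126	177	77	116
T027	91	177	65	104
T028	86	104	62	72
T029	69	128	44	77
T030	94	143	91	101
T031	88	189	87	109
T032	90	158	67	113
T033	64	97	37	77
T034	78	138	54	85
T035	52	108	34	43
T036	73	79	46	53
T037	99	121	65	96
T038	117	215	109	139
T039	163	241	126	154
T040	15	18	13	21
T041	70	93	35	66
T042	33	59	22	26
T043	56	66	40	58
T044	98	147	49	75
T045	238	396	188	231
T046	66	145	59	84
T047	57	102	52	89
T048	123	211	92	133
T049	85	129	51	76
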