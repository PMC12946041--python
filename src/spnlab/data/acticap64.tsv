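label	x	y	z
Fp1	-26.74	76.24	-6.35
Fz	0.28	53.16	60.38
F3	-45.65	48.25	38.33
F7	-63.83	38.59	-10.37
FT9	-76.38	13.23	-45.81
FC5	-70.15	16.94	22.22
FC1	-30.94	23.63	72.67
C3	-59.38	-10.57	58.47
T7	-76.46	-14.55	-8.49
TP9	-77.78	-42.26	-41.52
CP5	-72.31	-42.29	28.12
CP1	-32.26	-42.96	82.96
Pz	0.29	-73.69	75.05
P3	-48.16	-71.58	50.82
P7	-65.81	-66.73	-2.26
O1	-26.72	-102.16	8.03
Oz	0.10	-104.38	13.32
O2	27.11	-101.89	7.99
P4	50.57	-71.37	51.38
P8	66.37	-66.38	-2.31
TP10	78.28	-42.73	-41.67
CP6	75.70	-41.88	28.35
CP2	34.87	-42.77	82.40
Cz	0.36	-8.33	91.07
C4	60.98	-9.90	57.76
T8	77.29	-13.65	-8.62
FT10	76.42	13.05	-45.91
FC6	72.26	18.11	22.20
FC2	31.60	24.02	71.60
F4	47.09	49.34	37.08
F8	66.36	40.36	-10.90
Fp2	27.14	77.13	-6.43
AF7	-49.82	62.30	-9.62
AF3	-30.62	69.81	19.28
AFz	0.21	73.38	32.18
F1	-24.98	51.72	54.82
F5	-58.57	43.64	15.37
FT7	-73.38	12.83	-10.12
FC3	-54.67	20.64	50.46
C1	-32.85	-9.07	81.54
C5	-72.93	-12.50	26.49
TP7	-77.07	-41.81	-6.41
CP3	-57.74	-42.71	59.62
P1	-26.00	-73.16	68.53
P5	-61.12	-69.31	25.78
PO7	-49.82	-88.60	2.54
PO3	-33.17	-91.62	33.77
POz	0.20	-92.83	45.98
PO4	33.42	-91.62	33.07
PO8	50.57	-88.69	2.48
P6	61.67	-68.96	25.52
P2	29.00	-73.12	69.70
CPz	0.35	-42.99	90.33
CP4	60.52	-42.37	59.58
TP8	77.72	-41.38	-6.48
C6	75.82	-11.61	26.54
C2	34.22	-8.74	80.32
FC4	56.59	21.55	50.54
FT8	74.33	14.01	-10.29
F6	61.70	45.27	14.87
AF8	50.64	63.28	-9.77
AF4	32.44	70.61	19.95
F2	26.81	52.33	54.09
Iz	0.00	-107.71	-20.97
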