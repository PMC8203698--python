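algorithm	20	30	40	50	60	70	80	90	100
proposed	9.41	8.87	5.89	5.39	4.98	4.62	4.38	4.07	3.49
GB	8.74	8.37	8.22	8.17	7.74	7.67	5.38	4.79	4.30
ANN	11.95	10.74	9.54	8.11	8.02	7.59	7.43	6.74	6.41
EN	10.56	10.37	10.06	9.57	8.91	8.39	7.32	7.22	6.79
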