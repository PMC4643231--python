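# Literature-derived per-bond chain-scission probabilities (lambda) for seven
# archaeological dental-calculus sites, ordered by increasing thermal age.
# lambda is dimensionless (probability of scission per internal bond).
site	time_period	lam
Middenbeemster (Netherlands)	1611-1866 CE	0.0006
Tickhill (UK)	ca. 1450-1600 CE	0.0021
Rupert's Valley (St. Helena)	1840-1872 CE	0.0030
Samdzong (Nepal)	ca. 400-650 CE	0.0045
Camino del Molino (Spain)	ca. 2340-2920 BCE	0.0149
Anse a la Gourde (Guadeloupe)	ca. 975-1395 CE	0.0701
Lavoutte (St. Lucia)	ca. 990-1255 CE	0.0863
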