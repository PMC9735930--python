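# Docking scores (kcal/mol) and experimental inhibition potencies (IC50, uM)
# for the 16 triazole-linked kojic-acid analogs against tyrosinase.
ligand_id	docking_score	ic50_um
6a	-120.78	1.33
6b	-132.33	0.88
6c	-132.03	0.69
6d	-128.15	6.80
6e	-125.68	1.07
6f	-136.38	0.99
6g	-129.55	1.12
6h	-139.06	6.29
6i	-132.92	0.52
6j	-135.60	2.64
6k	-132.85	1.32
6l	-125.93	1.24
6m	-130.46	0.87
6n	-130.17	0.74
6o	-130.15	0.06
6p	-131.51	0.30
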