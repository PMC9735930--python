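# Ensemble-averaged ligand-surrounding interaction energies (kcal/mol) for
# 13 kojic-acid analogs bound to tyrosinase and free in water, with replica
# standard errors, plus the reported LIE and IC50-derived free energies
# (reference columns, 5 replicas x 2 ns each).
ligand_id	free_vdw	free_vdw_sem	free_ele	free_ele_sem	bound_vdw	bound_vdw_sem	bound_ele	bound_ele_sem	dg_lie_ref	dg_lie_sem_ref	dg_exp_ref
6a	-26.21	0.01	-26.70	0.49	-49.16	0.98	-84.09	0.24	-8.03	0.45	-8.07
6b	-26.31	0.06	-26.91	0.10	-46.90	0.34	-85.71	0.63	-8.13	0.34	-8.31
6c	-27.77	0.02	-25.57	0.17	-49.79	0.41	-84.45	0.70	-8.41	0.40	-8.46
6e	-26.24	0.03	-26.97	0.31	-46.53	0.21	-85.27	0.76	-7.89	0.44	-8.20
6f	-27.61	0.02	-25.32	0.18	-50.79	0.90	-82.86	0.89	-8.13	0.56	-8.24
6h	-28.48	0.08	-30.39	0.45	-51.28	0.29	-89.28	0.78	-6.20	0.47	-7.14
6i	-29.42	0.04	-29.93	0.02	-55.29	0.51	-89.10	0.26	-9.21	0.20	-8.63
6j	-30.14	0.08	-42.95	0.30	-55.83	0.37	-99.47	0.97	-7.07	0.53	-7.66
6l	-28.59	0.03	-28.16	0.16	-50.52	0.68	-86.78	1.01	-8.30	0.56	-8.11
6m	-31.90	0.10	-33.77	0.61	-57.72	0.40	-90.52	0.99	-8.31	0.68	-8.32
6n	-28.72	0.09	-29.18	0.74	-49.41	0.79	-88.77	0.90	-8.44	0.76	-8.42
6o	-29.99	0.30	-27.33	0.05	-61.99	0.37	-87.15	0.24	-10.56	0.23	-9.91
6p	-30.01	0.20	-27.97	0.43	-61.40	0.91	-86.21	0.22	-9.80	0.44	-8.95
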