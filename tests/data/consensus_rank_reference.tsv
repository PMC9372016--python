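tissue	timepoint	cell_type	ed_rank	svm_rank	deg_rank	avg_rank
Blood	24-h	CD8+ T cells	3	1	1	1.67
Blood	24-h	CD4+ T cells	2	5	1	2.67
Blood	24-h	Ly6c+ monocytes	5	3	3	3.67
Blood	7-day	CD8+ T cells	4	1	1	2.00
Blood	7-day	Ly6c+ monocytes	3	2	3	2.67
Blood	7-day	B cells	1	3	5	3.00
Frontal cortex	24-h	Astrocytes	1	2	1	1.33
Frontal cortex	24-h	Layer 2/3 neurons	8	1	2	3.67
Frontal cortex	24-h	Endothelial	2	6	4	4.00
Frontal cortex	7-day	Endothelial	2	7	5	4.67
Frontal cortex	7-day	Astrocytes	1	8	5	4.67
Frontal cortex	7-day	Activated microglia	3	11	2	5.33
Hippocampus	24-h	Astrocytes	1	1	1	1.00
Hippocampus	24-h	Activated microglia	2	4	2	2.67
Hippocampus	24-h	Microglia	5	5	3	4.33
Hippocampus	7-day	Oligodendrocytes	1	1	5	2.33
Hippocampus	7-day	Astrocytes	4	2	2	2.67
Hippocampus	7-day	Choroid plexus epithelial	6	5	2	4.33
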