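feature_id	class	citation
mmu-miR-29b	oncomir	context-dependent oncomir in lung carcinoma
mmu-miR-21	oncomir	canonical oncomir, anti-apoptotic
mmu-miR-10b	oncomir	pro-metastatic oncomir
mmu-miR-451a	suppressor	tumour suppressor, erythroid lineage
mmu-miR-17	oncomir	miR-17~92 cluster oncomir
mmu-miR-18a	oncomir	miR-17~92 cluster oncomir
mmu-miR-145	suppressor	tumour suppressor, represses c-Myc
mmu-miR-31	oncomir	lung adenocarcinoma oncomir
mmu-let-7g	suppressor	let-7 family, represses RAS/HMGA2
mmu-let-7a	suppressor	let-7 family tumour suppressor
mmu-let-7b	suppressor	let-7 family tumour suppressor
mmu-let-7c	suppressor	let-7 family tumour suppressor
mmu-let-7d	suppressor	let-7 family tumour suppressor
mmu-let-7e	suppressor	let-7 family tumour suppressor
mmu-let-7f	suppressor	let-7 family tumour suppressor
mmu-let-7i	suppressor	let-7 family tumour suppressor
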