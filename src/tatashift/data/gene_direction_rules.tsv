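# Curated per-gene mapping from expression change to atherogenesis direction,
# compiled from the study's marker annotations (citation = disease/physiology
# rationale recorded with the markers).
gene	on_over	on_under	citation
CETP	accel	decel	CETP excess is atherogenic; deficit is athero-protective (hyperalphalipoproteinemia)
MBL2	accel	accel	MBL2 deficit and excess quicken late and early atherogenesis respectively
F3	accel	decel	thromboplastin excess causes infarction/thrombosis; antithromboplastin slows atherogenesis
TPI1	unknown	accel	TPI1 deficiency: hemolytic anemia / traumatic-ischemic complications
HBB	accel	decel	thalassemia is athero-protective; extracellular HBB releases atherogenic heme
HBD	accel	decel	thalassemia is athero-protective
ACKR1	accel	decel	ACKR1 underexpression reduces atherogenesis (mouse model)
NOS2	accel	decel	NO excess accelerates atherogenesis; NOS2 inhibition slows it
F7	accel	accel	both F7 deficit and excess are atherogenic factors
SOD1	unknown	accel	SOD1 deficiency (familial ALS) accelerates atherogenesis
INS	accel	accel	hyper- and hypoinsulinemia both speed up atherogenesis
MMP12	accel	accel	macrophage-elastase excess and deficit both accelerate atherogenesis
GCG	unknown	accel	hypoglucagonemia raises postprandial INS:GCG ratio
LEP	decel	accel	hypoleptinemia causes obesity; LEP excess protects
APOA1	unknown	accel	APOA1 underexpression: obesity and atherosclerosis
HTR2C	accel	unknown	HTR2C overexpression causes obesity
IL1B	accel	decel	IL1B excess is pro-atherogenic; deficiency marks successful treatment
ADH7	unknown	accel	ADH7 underexpression: esophageal cancer comorbid with atherosclerosis
HSD17B1	accel	decel	HSD17B1 excess accelerates; insufficiency marks anti-atherosclerotic therapy
MLH1	decel	accel	improved DNA mismatch repair slows atherogenesis
RET	decel	accel	RET deficiency dysregulates athero-protector pentraxin-3
ESR2	unknown	accel	ESR2 deficit marks the calcification stage of atherogenesis
DHFR	decel	accel	DHFR excess is athero-protective
COMT	decel	decel	estradiol (substrate) and 2-methoxyestradiol (metabolite) are athero-protectors
TGFBR2	accel	accel	deficit: inflammatory plaque phenotype; excess: hypertension
FGFR2	accel	decel	FGFR2 antagonist blocks atherogenesis in a murine model
POLG	decel	accel	POLG deficiency elevates mitochondrial DNA damage
PGC1A	decel	decel	both PGC1A down- and upregulation reported athero-protective
TFAM	accel	decel	TFAM excess pro-atherogenic; adipose TFAM deletion athero-protective
ATM	decel	accel	ATM excess is an athero-protector; ATM-deficient atherosclerosis model
MIR10B	accel	decel	miR-10b excess over-inhibits ABCA1; deficit athero-protective
MIR21	decel	unknown	miR-21 downregulation reduces plaque calcification
MIR143	decel	accel	miR-143 excess prevents foam-cell transformation
MIR145	decel	accel	miR-145 excess is an athero-protector
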