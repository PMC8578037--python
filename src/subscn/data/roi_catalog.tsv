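roi_name	hemisphere	structure_group
L_Caudate	L	basal_ganglia
L_Putamen	L	basal_ganglia
L_Accumbens-area	L	basal_ganglia
L_Pallidum	L	basal_ganglia
L_Lateral-nucleus	L	amygdala
L_Basal-nucleus	L	amygdala
L_Accessory-Basal-nucleus	L	amygdala
L_Anterior-amygdaloid-area	L	amygdala
L_Central-nucleus	L	amygdala
L_Medial-nucleus	L	amygdala
L_Cortical-nucleus	L	amygdala
L_Corticoamygdaloid-transition	L	amygdala
L_Paralaminar-nucleus	L	amygdala
L_Hippocampal-tail	L	hippocampus
L_Subiculum	L	hippocampus
L_Presubiculum	L	hippocampus
L_Parasubiculum	L	hippocampus
L_CA1	L	hippocampus
L_CA2	L	hippocampus
L_CA3	L	hippocampus
L_CA4	L	hippocampus
L_GC-ML-DG	L	hippocampus
L_Molecular-layer-HP	L	hippocampus
L_Fimbria	L	hippocampus
L_HATA	L	hippocampus
L_AV	L	thalamus
L_LD	L	thalamus
L_LP	L	thalamus
L_VA	L	thalamus
L_VAmc	L	thalamus
L_VLa	L	thalamus
L_VLp	L	thalamus
L_VPL	L	thalamus
L_VM	L	thalamus
L_CeM	L	thalamus
L_CL	L	thalamus
L_CM	L	thalamus
L_Pc	L	thalamus
L_Pf	L	thalamus
L_Pt	L	thalamus
L_MV-Re	L	thalamus
L_MDm	L	thalamus
L_MDl	L	thalamus
L_LGN	L	thalamus
L_MGN	L	thalamus
L_L-Sg	L	thalamus
L_PuA	L	thalamus
L_PuM	L	thalamus
L_PuI	L	thalamus
L_PuL	L	thalamus
R_Caudate	R	basal_ganglia
R_Putamen	R	basal_ganglia
R_Accumbens-area	R	basal_ganglia
R_Pallidum	R	basal_ganglia
R_Lateral-nucleus	R	amygdala
R_Basal-nucleus	R	amygdala
R_Accessory-Basal-nucleus	R	amygdala
R_Anterior-amygdaloid-area	R	amygdala
R_Central-nucleus	R	amygdala
R_Medial-nucleus	R	amygdala
R_Cortical-nucleus	R	amygdala
R_Corticoamygdaloid-transition	R	amygdala
R_Paralaminar-nucleus	R	amygdala
R_Hippocampal-tail	R	hippocampus
R_Subiculum	R	hippocampus
R_Presubiculum	R	hippocampus
R_Parasubiculum	R	hippocampus
R_CA1	R	hippocampus
R_CA2	R	hippocampus
R_CA3	R	hippocampus
R_CA4	R	hippocampus
R_GC-ML-DG	R	hippocampus
R_Molecular-layer-HP	R	hippocampus
R_Fimbria	R	hippocampus
R_HATA	R	hippocampus
R_AV	R	thalamus
R_LD	R	thalamus
R_LP	R	thalamus
R_VA	R	thalamus
R_VAmc	R	thalamus
R_VLa	R	thalamus
R_VLp	R	thalamus
R_VPL	R	thalamus
R_VM	R	thalamus
R_CeM	R	thalamus
R_CL	R	thalamus
R_CM	R	thalamus
R_Pc	R	thalamus
R_Pf	R	thalamus
R_Pt	R	thalamus
R_MV-Re	R	thalamus
R_MDm	R	thalamus
R_MDl	R	thalamus
R_LGN	R	thalamus
R_MGN	R	thalamus
R_L-Sg	R	thalamus
R_PuA	R	thalamus
R_PuM	R	thalamus
R_PuI	R	thalamus
R_PuL	R	thalamus
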