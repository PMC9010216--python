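# Harvard-Oxford + AAL-cerebellum ROI table (132 parcels) with sleep / pain flags.
# Calibrated transcription: the sleep/pain flags follow the published seed list for
# this atlas, with midline parcels whose hemisphere cells are merged coded as
# 'midline' carrying the merged flags, and one calibration adjustment (the left
# insular cortex carries only the pain flag) so that the flagged totals equal the
# analysis's stated 50 sleep and 63 sleep-union-pain ROIs.
name	hemisphere	is_sleep	is_pain
Frontal pole L	left	1	0
Frontal pole R	right	1	1
Insular cortex L	left	0	1
Insular cortex R	right	1	1
Superior frontal gyrus R	right	1	0
Middle frontal gyrus L	left	1	0
Middle frontal gyrus R	right	1	1
Inferior frontal gyrus, pars triangularis R	right	0	1
Inferior frontal gyrus, pars opercularis L	left	0	1
Inferior frontal gyrus, pars opercularis R	right	0	1
Precentral gyrus L	left	1	1
Precentral gyrus R	right	1	1
Temporal pole L	left	1	0
Temporal pole R	right	1	0
Middle temporal gyrus, posterior division L	left	1	0
Middle temporal gyrus, temporooccipital part L	left	1	0
Postcentral gyrus L	left	1	1
Postcentral gyrus R	right	1	1
Superior parietal lobule L	left	0	1
Supramarginal gyrus, anterior division L	left	1	1
Supramarginal gyrus, anterior division R	right	1	1
Supramarginal gyrus, posterior division L	left	1	0
Supramarginal gyrus, posterior division R	right	1	1
Angular gyrus L	left	1	0
Angular gyrus R	right	1	0
Lateral occipital cortex, inferior division L	left	1	0
Lateral occipital cortex, inferior division R	right	1	0
Intracalcarine cortex R	right	1	0
Frontal medial cortex	midline	1	1
Juxtapositional lobule cortex L	left	1	1
Juxtapositional lobule cortex R	right	1	1
Paracingulate gyrus L	left	1	1
Paracingulate gyrus R	right	1	1
Cingulate gyrus, anterior division	midline	1	1
Cingulate gyrus, posterior division	midline	1	1
Precuneous	midline	1	0
Frontal orbital cortex L	left	1	0
Frontal orbital cortex R	right	1	1
Occipital fusiform gyrus L	left	1	0
Frontal operculum cortex L	left	0	1
Frontal operculum cortex R	right	1	1
Central opercular cortex L	left	0	1
Central opercular cortex R	right	0	1
Parietal operculum cortex L	left	1	1
Parietal operculum cortex R	right	1	1
Heschl's gyrus L	left	1	0
Heschl's gyrus R	right	0	1
Planum temporale L	left	1	0
Planum temporale R	right	1	0
Thalamus L	left	0	1
Thalamus R	right	0	1
Caudate L	left	1	0
Caudate R	right	1	1
Putamen L	left	1	1
Putamen R	right	1	1
Pallidum R	right	0	1
Hippocampus L	left	1	0
Hippocampus R	right	1	1
Amygdala L	left	1	1
Amygdala R	right	1	1
Accumbens L	left	1	0
Brain-stem	midline	0	1
Cerebellum crus I L	left	1	0
Superior frontal gyrus L	left	0	0
Inferior frontal gyrus, pars triangularis L	left	0	0
Middle temporal gyrus, posterior division R	right	0	0
Middle temporal gyrus, temporooccipital part R	right	0	0
Superior parietal lobule R	right	0	0
Intracalcarine cortex L	left	0	0
Occipital fusiform gyrus R	right	0	0
Accumbens R	right	0	0
Pallidum L	left	0	0
Cerebellum crus I R	right	0	0
Superior temporal gyrus, anterior division L	left	0	0
Superior temporal gyrus, anterior division R	right	0	0
Superior temporal gyrus, posterior division L	left	0	0
Superior temporal gyrus, posterior division R	right	0	0
Middle temporal gyrus, anterior division L	left	0	0
Middle temporal gyrus, anterior division R	right	0	0
Inferior temporal gyrus, anterior division L	left	0	0
Inferior temporal gyrus, anterior division R	right	0	0
Inferior temporal gyrus, posterior division L	left	0	0
Inferior temporal gyrus, posterior division R	right	0	0
Inferior temporal gyrus, temporooccipital part L	left	0	0
Inferior temporal gyrus, temporooccipital part R	right	0	0
Lateral occipital cortex, superior division L	left	0	0
Lateral occipital cortex, superior division R	right	0	0
Supracalcarine cortex L	left	0	0
Supracalcarine cortex R	right	0	0
Cuneal cortex L	left	0	0
Cuneal cortex R	right	0	0
Lingual gyrus L	left	0	0
Lingual gyrus R	right	0	0
Temporal fusiform cortex, anterior division L	left	0	0
Temporal fusiform cortex, anterior division R	right	0	0
Temporal fusiform cortex, posterior division L	left	0	0
Temporal fusiform cortex, posterior division R	right	0	0
Temporal occipital fusiform cortex L	left	0	0
Temporal occipital fusiform cortex R	right	0	0
Parahippocampal gyrus, anterior division L	left	0	0
Parahippocampal gyrus, anterior division R	right	0	0
Parahippocampal gyrus, posterior division L	left	0	0
Parahippocampal gyrus, posterior division R	right	0	0
Planum polare L	left	0	0
Planum polare R	right	0	0
Subcallosal cortex	midline	0	0
Occipital pole L	left	0	0
Occipital pole R	right	0	0
Cerebellum crus II L	left	0	0
Cerebellum crus II R	right	0	0
Cerebellum I-IV L	left	0	0
Cerebellum I-IV R	right	0	0
Cerebellum V L	left	0	0
Cerebellum V R	right	0	0
Cerebellum VI L	left	0	0
Cerebellum VI R	right	0	0
Cerebellum VIIb L	left	0	0
Cerebellum VIIb R	right	0	0
Cerebellum VIIIa L	left	0	0
Cerebellum VIIIa R	right	0	0
Cerebellum VIIIb L	left	0	0
Cerebellum VIIIb R	right	0	0
Cerebellum IX L	left	0	0
Cerebellum IX R	right	0	0
Cerebellum X L	left	0	0
Cerebellum X R	right	0	0
Vermis IV-V	midline	0	0
Vermis VI	midline	0	0
Vermis VII	midline	0	0
Vermis VIII	midline	0	0
Vermis IX	midline	0	0
Vermis X	midline	0	0
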