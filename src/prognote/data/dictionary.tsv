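no	NEGEX
not	NEGEX
absent	NEGEX
denies	NEGEX
negative for	NEGEX
without evidence of	NEGEX
adequate to rule her out	NEGEX
ruled out	NEGEX
free of	NEGEX
mother	FAMILY
father	FAMILY
brother	FAMILY
sister	FAMILY
wife	FAMILY
husband	FAMILY
daughter	FAMILY
son	FAMILY
family history	FAMILY
suspicion	RISK
suspicious	RISK
probable	RISK
possible	RISK
likely	RISK
concerning for	RISK
worrisome	RISK
cannot exclude	RISK
increase	QUAL
increasing	QUAL
decrease	QUAL
decreasing	QUAL
invasive	QUAL
diffuse	QUAL
stable	QUAL
enlarging	QUAL
improved	QUAL
worsening	QUAL
metastasis	METASTASIS
metastases	METASTASIS
metastatic	METASTASIS
bone metastasis	METASTASIS
lesion	LESION
mass	LESION
nodule	LESION
tumor	TUMOR
carcinoma	CARCINOMA
adenocarcinoma	CARCINOMA
malignancy	CARCINOMA
chemotherapy	CHEMO
chemo	CHEMO
cycle of chemotherapy	CHEMO
radiation	RADIOTHERAPY
radiotherapy	RADIOTHERAPY
palliative radiation	RADIOTHERAPY
pain	SYMPTOM
fatigue	SYMPTOM
nausea	SYMPTOM
dyspnea	SYMPTOM
anorexia	SYMPTOM
hospice	HOSPICE
comfort care	HOSPICE
comfort measures	HOSPICE
unresponsive	DETERIORATION
rapid decline	DETERIORATION
multiorgan failure	DETERIORATION
agonal	DETERIORATION
moribund	DETERIORATION
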