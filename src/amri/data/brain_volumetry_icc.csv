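location,icc
Amygdala,0.992
Basal ganglia,0.971
Cerebellum,0.995
Cerebrospinal fluid,0.651
Frontal,0.987
Frontal/parietal,0.928
Gray matter,0.985
Headfat,0.951
Hippocampus,0.993
Insular,0.996
Left amygdala,0.99
Left caudate,0.996
Left cortical white matter,0.997
Left hippocampus,0.989
Left pallidum,0.945
Left putamen,0.884
Left thalamus,0.954
Limbic,0.987
Occipital,0.961
Parietal,0.98
Right amygdala,0.989
Right caudate,0.993
Right cortical white matter,0.997
Right hippocampus,0.991
Right pallidum,0.972
Right putamen,0.946
Right thalamus,0.99
Temporal,0.96
Temporal/occipital,0.817
White matter,0.992
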