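species	Sample 1/27f/1492r	Sample 1/L5	Sample 1/L6	Sample 2/27f/1492r	Sample 2/L5	Sample 2/L6	Sample 3/27f/1492r	Sample 3/L5	Sample 3/L6
Enterococcus avium	0	0	0	0	0	0	0	0.07	0
Enterococcus casseliflavus	0	0	0	0	0	0.07	0	0	0
Lactobacillus acidophilus	0	0	0.07	0	0	0	0	0	0
Lactobacillus delbrueckii	0.07	0.26	0.07	0.08	0.19	0.07	0	0	0
Lactobacillus helveticus	0	0	0	0	0.06	0	0	0	0
Lactobacillus pentosus	0	0.06	0	0	0	0	0	0	0
Lactobacillus rogosae	0.35	0.26	2.36	0.15	0.06	1.77	1.78	0.7	3.57
Lactobacillus ruminis	0	0.13	0	0.08	0.88	0.2	0	0	0
Lactococcus garvieae	0	0.06	0.07	0	0.06	0	0	0	0
Leuconostoc lactis	0	0.13	0	0	0	0	0	0	0
Streptococcus agalactiae	0	0	0	0	0.06	0	0	0	0
Streptococcus infantarius	0	0	0	0	0.06	0	0	0	0
Streptococcus mutans	0	0	0	0	0.06	0	0	0	0
Streptococcus parasanguinis	0	0	0	0	0.06	0.13	0	0.07	0
Streptococcus salivarius	0.35	10.89	1.64	0.3	9.78	3.02	0.07	4.81	0.14
Streptococcus sanguinis	0	0.06	0	0	0.13	0.07	0	0.07	0
Weissella confusa	0	0.58	0.33	0	0.19	0.07	0	0	0
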