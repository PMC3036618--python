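gene_id	n_reagents	n_scoring	n_nonscoring	category	expressed
Abl	4	4	0	1	Yes
CycA	3	3	0	1	Yes
dome	3	3	0	1	Yes
hop	3	3	0	1	Yes
mts	2	2	0	1	Yes
CycE	3	2	1	2	Yes
Pp4-19C	4	2	2	2	Yes
CG17090	3	2	1	2	Yes
puc	3	2	1	2	Yes
CG34318 | CG8179	4	1	3	3	No
CanA1	3	1	2	3	No
CG4839	3	1	2	3	No
CG7597	3	1	2	3	Yes
CG9389	3	1	2	3	No
mtm	3	1	2	3	Yes
Pi3K21B	3	1	2	3	Yes
smi35A	3	1	2	3	Yes
Src42A	3	1	2	3	Yes
CG8509	2	1	1	3	No
gskt	2	1	1	3	No
htl	2	1	1	3	No
Myt1	2	1	1	3	Yes
Pp1-Y2	2	1	1	3	No
S6k	2	1	1	3	Yes
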