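gene	modification	role
METTL3	m6A	writer
METTL14	m6A	writer
METTL16	m6A	writer
WTAP	m6A	writer
VIRMA	m6A	writer
ZC3H13	m6A	writer
RBM15	m6A	writer
RBM15B	m6A	writer
YTHDC2	m6A	reader
HNRNPC	m6A	reader
HNRNPA2B1	m6A	reader
FMR1	m6A	reader
LRPPRC	m6A	reader
IGFBP1	m6A	reader
IGFBP2	m6A	reader
IGFBP3	m6A	reader
IGF2BP1	m6A	reader
IGF2BP2	m6A	reader
IGF2BP3	m6A	reader
RBMX	m6A	reader
ELAVL1	m6A	reader
FTO	m6A	eraser
ALKBH5	m6A	eraser
NOP2	m5C	writer
NSUN2	m5C	writer
NSUN3	m5C	writer
NSUN4	m5C	writer
NSUN5	m5C	writer
NSUN6	m5C	writer
NSUN7	m5C	writer
DNMT1	m5C	writer
DNMT3A	m5C	writer
DNMT3B	m5C	writer
TRDMT1	m5C	writer
ALYREF	m5C	reader
TET1	m5C	eraser
TET2	m5C	eraser
TET3	m5C	eraser
TRMT6	m1A	writer
TRMT61A	m1A	writer
TRMT61B	m1A	writer
TRMT10C	m1A	writer
YTHDF1	m1A	reader
YTHDF2	m1A	reader
YTHDF3	m1A	reader
YTHDC1	m1A	reader
ALKBH1	m1A	eraser
ALKBH3	m1A	eraser
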