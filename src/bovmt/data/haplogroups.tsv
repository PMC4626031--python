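# Default taurine haplogroup configuration.
# Clade structure follows the taurine cattle mtDNA phylogeny (P, Q, R, macro-T).
# Only 15953G (the C->G transversion distinguishing Q from T) is an established
# diagnostic position; motifs with status=synthetic are deterministic placeholders
# intended to be replaced by curated motifs. I (zebu) and R are placeholder nodes.
name	parent	defining_variants	status
root			verified
PQT	root	1027,9682	synthetic
I	root	901,2301,7040	placeholder
R	root	1501,8250	placeholder
P	PQT	2056,4310,12785	synthetic
QT	PQT	3451	synthetic
Q	QT	15953G,5480,7925	partial:15953G verified
Q1	Q	3566,9102	synthetic
Q1a	Q1	11459	synthetic
Q2	Q	6340,12066	synthetic
T	QT	2129,8541	synthetic
T1'2'3	T	5164	synthetic
T1	T1'2'3	3388,10541	synthetic
T1a	T1	12953	synthetic
T1b	T1	4219	synthetic
T1b1	T1b	13310	synthetic
T1c	T1	6803	synthetic
T1c1	T1c	2837	synthetic
T1c1a	T1c1	14277	synthetic
T1d	T1	9402	synthetic
T1d1	T1d	1741	synthetic
T1e	T1	15210	synthetic
T1f	T1	7108	synthetic
T2	T1'2'3	4646,13803	synthetic
T3	T1'2'3	5752	synthetic
T3a	T3	8943	synthetic
T4	T3a	10187	synthetic
T3b	T3	12420	synthetic
T5	T	3950,14650	synthetic
T5a	T5	6520	synthetic
T5b	T5	11873	synthetic
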