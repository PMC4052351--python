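	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	-0.28	0.21	0.132	0.132	-0.334	0.132	0.132	-0.109	0.109	-0.49	-0.436	0.163	-0.288	-0.358	-0.016	-0.078	-0.086	-0.07	-0.039	-0.467
R	0.21	0.7	0.622	0.622	0.156	0.622	0.622	0.381	0.599	-0.0	0.054	0.653	0.202	0.132	0.474	0.412	0.404	0.42	0.451	0.023
N	0.132	0.622	0.544	0.544	0.078	0.544	0.544	0.303	0.521	-0.078	-0.023	0.576	0.124	0.054	0.397	0.334	0.327	0.342	0.373	-0.054
D	0.132	0.622	0.544	0.544	0.078	0.544	0.544	0.303	0.521	-0.078	-0.023	0.576	0.124	0.054	0.397	0.334	0.327	0.342	0.373	-0.054
C	-0.334	0.156	0.078	0.078	-0.389	0.078	0.078	-0.163	0.054	-0.544	-0.49	0.109	-0.342	-0.412	-0.07	-0.132	-0.14	-0.124	-0.093	-0.521
Q	0.132	0.622	0.544	0.544	0.078	0.544	0.544	0.303	0.521	-0.078	-0.023	0.576	0.124	0.054	0.397	0.334	0.327	0.342	0.373	-0.054
E	0.132	0.622	0.544	0.544	0.078	0.544	0.544	0.303	0.521	-0.078	-0.023	0.576	0.124	0.054	0.397	0.334	0.327	0.342	0.373	-0.054
G	-0.109	0.381	0.303	0.303	-0.163	0.303	0.303	0.062	0.28	-0.319	-0.264	0.334	-0.117	-0.187	0.156	0.093	0.086	0.101	0.132	-0.296
H	0.109	0.599	0.521	0.521	0.054	0.521	0.521	0.28	0.498	-0.101	-0.047	0.552	0.101	0.031	0.373	0.311	0.303	0.319	0.35	-0.078
I	-0.49	-0.0	-0.078	-0.078	-0.544	-0.078	-0.078	-0.319	-0.101	-0.7	-0.646	-0.047	-0.498	-0.568	-0.226	-0.288	-0.296	-0.28	-0.249	-0.677
L	-0.436	0.054	-0.023	-0.023	-0.49	-0.023	-0.023	-0.264	-0.047	-0.646	-0.591	0.008	-0.443	-0.513	-0.171	-0.233	-0.241	-0.226	-0.194	-0.622
K	0.163	0.653	0.576	0.576	0.109	0.576	0.576	0.334	0.552	-0.047	0.008	0.607	0.156	0.086	0.428	0.366	0.358	0.373	0.404	-0.023
M	-0.288	0.202	0.124	0.124	-0.342	0.124	0.124	-0.117	0.101	-0.498	-0.443	0.156	-0.296	-0.366	-0.023	-0.086	-0.093	-0.078	-0.047	-0.474
F	-0.358	0.132	0.054	0.054	-0.412	0.054	0.054	-0.187	0.031	-0.568	-0.513	0.086	-0.366	-0.436	-0.093	-0.156	-0.163	-0.148	-0.117	-0.544
P	-0.016	0.474	0.397	0.397	-0.07	0.397	0.397	0.156	0.373	-0.226	-0.171	0.428	-0.023	-0.093	0.249	0.187	0.179	0.194	0.226	-0.202
S	-0.078	0.412	0.334	0.334	-0.132	0.334	0.334	0.093	0.311	-0.288	-0.233	0.366	-0.086	-0.156	0.187	0.124	0.117	0.132	0.163	-0.264
T	-0.086	0.404	0.327	0.327	-0.14	0.327	0.327	0.086	0.303	-0.296	-0.241	0.358	-0.093	-0.163	0.179	0.117	0.109	0.124	0.156	-0.272
W	-0.07	0.42	0.342	0.342	-0.124	0.342	0.342	0.101	0.319	-0.28	-0.226	0.373	-0.078	-0.148	0.194	0.132	0.124	0.14	0.171	-0.257
Y	-0.039	0.451	0.373	0.373	-0.093	0.373	0.373	0.132	0.35	-0.249	-0.194	0.404	-0.047	-0.117	0.226	0.163	0.156	0.171	0.202	-0.226
V	-0.467	0.023	-0.054	-0.054	-0.521	-0.054	-0.054	-0.296	-0.078	-0.677	-0.622	-0.023	-0.474	-0.544	-0.202	-0.264	-0.272	-0.257	-0.226	-0.653
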