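# Dayhoff (1978) equilibrium amino-acid frequencies
A	0.0871269129
R	0.0409039591
N	0.0404319596
D	0.0468719531
C	0.0334739665
Q	0.0382549617
E	0.0495299505
G	0.0886119114
H	0.0336179664
I	0.0368859631
L	0.0853569146
K	0.0804819195
M	0.0147529852
F	0.0397719602
P	0.0506799493
S	0.0695769304
T	0.0585419415
W	0.0104939895
Y	0.0299159701
V	0.0647179353
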