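aa,ca,cb,co
A,52.5,19.1,177.8
R,56.0,30.9,176.3
N,53.1,38.9,175.2
D,54.2,41.1,176.3
C,58.2,28.0,174.6
Q,55.7,29.4,176.0
E,56.6,29.9,176.6
G,45.1,,174.9
H,55.0,29.0,174.1
I,61.1,38.8,176.4
L,55.1,42.4,177.6
K,56.2,33.1,176.6
M,55.4,32.9,176.3
F,57.7,39.6,175.8
P,63.3,31.7,177.3
S,58.3,63.8,174.6
T,61.8,69.8,174.7
W,57.5,29.6,176.1
Y,57.9,38.8,175.9
V,62.2,32.9,176.3
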