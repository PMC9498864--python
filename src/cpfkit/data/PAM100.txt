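#  PAM100 substitution matrix, Dayhoff-derived, from the NCBI matrix collection.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  X
A   4  -3  -1  -1  -3  -2   0   1  -3  -2  -3  -3  -2  -5   1   1   1  -7  -4   0  -1
R  -3   7  -2  -4  -5   1  -3  -5   1  -3  -5   2  -1  -6  -1  -1  -3   1  -6  -4  -2
N  -1  -2   5   3  -5  -1   1  -1   2  -3  -4   1  -4  -5  -2   1   0  -5  -2  -3  -1
D  -1  -4   3   5  -7   0   4  -1  -1  -4  -6  -1  -5  -8  -3  -1  -2  -9  -6  -4  -2
C  -3  -5  -5  -7   9  -8  -8  -5  -4  -3  -8  -8  -7  -7  -4  -1  -4  -9  -1  -3  -5
Q  -2   1  -1   0  -8   6   2  -3   3  -4  -2   0  -2  -7  -1  -2  -2  -7  -6  -3  -2
E   0  -3   1   4  -8   2   5  -1  -1  -3  -5  -1  -4  -8  -2  -1  -2  -9  -5  -3  -2
G   1  -5  -1  -1  -5  -3  -1   5  -4  -5  -6  -3  -4  -6  -2   0  -2  -9  -7  -3  -2
H  -3   1   2  -1  -4   3  -1  -4   7  -4  -3  -2  -4  -3  -1  -2  -3  -4  -1  -3  -2
I  -2  -3  -3  -4  -3  -4  -3  -5  -4   6   1  -3   1   0  -4  -3   0  -7  -3   3  -2
L  -3  -5  -4  -6  -8  -2  -5  -6  -3   1   6  -4   3   0  -4  -4  -3  -3  -3   0  -3
K  -3   2   1  -1  -8   0  -1  -3  -2  -3  -4   5   0  -7  -3  -1  -1  -6  -6  -4  -2
M  -2  -1  -4  -5  -7  -2  -4  -4  -4   1   3   0   9  -1  -4  -3  -1  -6  -5   1  -2
F  -5  -6  -5  -8  -7  -7  -8  -6  -3   0   0  -7  -1   8  -6  -4  -5  -1   4  -3  -4
P   1  -1  -2  -3  -4  -1  -2  -2  -1  -4  -4  -3  -4  -6   7   0  -1  -7  -7  -3  -2
S   1  -1   1  -1  -1  -2  -1   0  -2  -3  -4  -1  -3  -4   0   4   2  -3  -4  -2  -1
T   1  -3   0  -2  -4  -2  -2  -2  -3   0  -3  -1  -1  -5  -1   2   5  -7  -4   0  -1
W  -7   1  -5  -9  -9  -7  -9  -9  -4  -7  -3  -6  -6  -1  -7  -3  -7  12  -2  -9  -6
Y  -4  -6  -2  -6  -1  -6  -5  -7  -1  -3  -3  -6  -5   4  -7  -4  -4  -2   9  -4  -4
V   0  -4  -3  -4  -3  -3  -3  -3  -3   3   0  -4   1  -3  -3  -2   0  -9  -4   5  -2
X  -1  -2  -1  -2  -5  -2  -2  -2  -2  -2  -3  -2  -2  -4  -2  -1  -1  -6  -4  -2  -2
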