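# Four-Gaussian X-ray atomic form factor coefficients for neutral atoms:
#   f(s) = sum_{i=1..4} a_i * exp(-b_i * s^2) + c,   s = sin(theta)/lambda [1/A]
# Columns: element a1 b1 a2 b2 a3 b3 a4 b4 c
H   0.489918  20.6593   0.262003   7.74039  0.196767  49.5519   0.049879   2.20159   0.001305
C   2.31000   20.8439   1.02000   10.2075   1.58860    0.568700 0.865000  51.6512    0.215600
N  12.2126     0.005700 3.13220    9.89330  2.01250   28.9975   1.16630    0.582600 -11.529
O   3.04850   13.2771   2.28680    5.70110  1.54630    0.323900 0.867000  32.9089    0.250800
S   6.90530    1.46790  5.20340   22.2151   1.43790    0.253600 1.58630   56.1720    0.866900
Cl 11.4604     0.010400 7.19640    1.16620  6.25560   18.5194   1.64550   47.7784   -9.5574
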