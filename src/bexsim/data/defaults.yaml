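# Published simulation parameter set (rates per day; amyloid in pmol/mg;
# cells per volume with 100 healthy cells at mouse age 2 months).
lambda_d: 6.1e-2
alpha_d: 17.0
mu_d: 5.0e-3
k_A: 3.5e-4
k_P0: 4.4e-2
k_B: 5.0e-2

N0: 100.0
Nd0: 0.0
A0: 0.25
P00: 0.0

B0: 0.0
t_B: 0.0
L: 1.0
r: 15.26
mode: none

rtol: 1.0e-8
atol: 1.0e-10
output_step: 0.5
seed: 0
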