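name = "default"

[chemostat]
kflow = 0.00016503504299046317
s_added = 1.0
C = 0.0003

[catalytic]
k_cat_nrf = 700.0
k_cat_nirB = 600.0
k_cat_nirC_in = 60.0
k_cat_nirC_out = 700.0
K_M_nrf = 0.03
K_M_nirB = 0.0021
K_M_nirC_in = 1.0
K_M_nirC_out = 1.0
k_dis_nrfA2B2u = 7000.0
k_dis_nirB2Dw = 600.0
k_dis_nirC5u = 240.0
k_dis_nirC5w = 48.0

[assembly]
K_dis_AB = 0.01
K_dis_A2B2 = 0.0001
K_dis_B2 = 0.05
K_dis_B2D = 0.0001
K_dis_C5 = 0.2
k_dis_AB = 6.2e-05
k_dis_A2B2 = 0.0001
k_dis_B2 = 0.00026
k_dis_B2D = 0.001
k_dis_C5 = 0.1

[turnover]
ks_nrf = 4.5e-06
ks_nir_B = 7.6e-07
ks_nir_C = 1.1e-05
ks_nir_D = 7.6e-07
delta_peripl = 6.0

[turnover.k_d]
NirC = 9.627044174443685e-05
NirC5 = 9.627044174443685e-05
NirB = 9.627044174443685e-05
NirD = 9.627044174443685e-05
NirB2 = 9.627044174443685e-05
NirB2D = 9.627044174443685e-05
NrfA_c = 9.627044174443685e-05
NrfB_c = 9.627044174443685e-05
NrfA = 9.627044174443684e-06
NrfB = 9.627044174443684e-06
NrfAB = 9.627044174443684e-06
NrfA2B2 = 9.627044174443684e-06

[nrf_expression]
delta_nrf_1 = 2.0
delta_nrf_2 = 0.02
K_nrf_1 = 0.15
K_nrf_2 = 1.5
h_nrf_1 = 2.0
h_nrf_2 = 2.5

[nir_expression]
delta_nir_1 = 4.0
delta_nir_2 = 40.0
K_nir_1 = 0.8
K_nir_2 = 3.0
h_nir_1 = 1.5
h_nir_2 = 4.0

[potential]
K_pmf_1 = 0.002
K_pmf_2 = 0.2
K_pmf_3 = 0.9
h_pmf_1 = 1.5
h_pmf_2 = 4.0
h_pmf_3 = 8.0
delta_pmf = 1.15
omega_1 = 30.0
omega_2 = 0.003

[translocation]
kt_nrf_cp = 0.01
kt_nrf_pc = 0.06
d_U = 6.0
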