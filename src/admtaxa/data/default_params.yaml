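# Benchmark ADM1 parameterisation plus the two-population rows
# (acetate/propionate degraders) and reactor operation settings.
C_aa: 0.03
C_ac: 0.0313
C_bac: 0.0313
C_bu: 0.025
C_ch: 0.0313
C_ch4: 0.0156
C_fa: 0.0217
C_li: 0.022
C_pr: 0.03
C_pro: 0.0268
C_sI: 0.03
C_su: 0.0313
C_va: 0.024
C_xI: 0.03
C_xc: 0.02786
HRT: 5.5
K_I_h2_c4: 1.0e-05
K_I_h2_fa: 5.0e-06
K_I_h2_pro: 3.5e-06
K_I_nh3_ac1: 0.3387
K_I_nh3_ac2: 0.0052
K_I_nh3_pro1: 0.4887
K_I_nh3_pro2: 0.0036
K_S_IN: 0.0001
K_S_aa: 0.3
K_S_ac1: 0.34
K_S_ac2: 0.15
K_S_c4: 0.2
K_S_fa: 0.4
K_S_h2: 7.0e-06
K_S_pro1: 0.34
K_S_pro2: 0.1
K_S_su: 0.5
N_I: 0.004285714285714286
N_aa: 0.007
N_bac: 0.005714285714285714
N_xc: 0.0026857142857142856
P_atm: 1.013
T_base: 298.15
T_op: 310.15
V_gas: 0.5
V_liq: 6.0
X_ac1_init: 0.06
X_pro1_init: 0.004
Y_aa: 0.08
Y_ac: 0.05
Y_c4: 0.06
Y_fa: 0.06
Y_h2: 0.06
Y_pro: 0.04
Y_su: 0.1
f_ac_aa: 0.4
f_ac_su: 0.41
f_bu_aa: 0.26
f_bu_su: 0.13
f_ch_xc: 0.2
f_fa_li: 0.95
f_h2_aa: 0.06
f_h2_su: 0.19
f_li_xc: 0.3
f_pr_xc: 0.2
f_pro_aa: 0.05
f_pro_su: 0.27
f_sI_xc: 0.1
f_va_aa: 0.23
f_xI_xc: 0.2
k_L_a: 200.0
k_dec: 0.02
k_dis: 0.5
k_hyd_ch: 10.0
k_hyd_li: 10.0
k_hyd_pr: 10.0
k_m_aa: 50.0
k_m_ac: 8.0
k_m_c4: 20.0
k_m_fa: 6.0
k_m_h2: 35.0
k_m_pro: 13.0
k_m_su: 30.0
k_p: 50000.0
pH_LL_aa: 4.0
pH_LL_ac: 6.0
pH_LL_h2: 5.0
pH_UL_aa: 5.5
pH_UL_ac: 7.0
pH_UL_h2: 6.0
temperature_correction: true
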