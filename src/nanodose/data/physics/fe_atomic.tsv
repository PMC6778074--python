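# Fe atomic relaxation data (K/L shells)
# columns: key  value
k_binding_kev	7.112
l_binding_kev	0.72
omega_k	0.340
kalpha_kev	6.404
kalpha_frac	0.882
kbeta_kev	7.058
kbeta_frac	0.118
k_auger_kev	5.67
l_auger_kev	0.60
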