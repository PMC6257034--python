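# Cultivar-level kinetic parameter sets for the mango softening model.
# Rates are referenced to T_ref = 295.15 K (22 degC); activation energies in kJ/mol.
# kfenz_ref is the lumped softening rate constant (k_f x k_enz, mol^-1 d^-1),
# kd_ref the enzyme-degradation rate constant (d^-1).
# The Kent kfenz_ref is fixed to 1 by convention (not estimated), which makes
# Kent Eth values absorb the overall scale.

keitt.kfenz_ref    = 0.099
keitt.kfenz_ref_sd = 0.007
keitt.kd_ref       = 0.219
keitt.kd_ref_sd    = 0.034
keitt.e_fenz       = 169.9
keitt.e_fenz_sd    = 3.6
keitt.e_d          = 0.01
keitt.e_d_sd       = 8.2

kent.kfenz_ref     = 1.0
kent.kd_ref        = 1.98
kent.kd_ref_sd     = 0.56
kent.e_fenz        = 194.5
kent.e_fenz_sd     = 17.6
kent.e_d           = 162.2
kent.e_d_sd        = 20.3
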