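descriptor,pls_ga,lasso,gpr
xtb_fukui_plus_N,1,1,0
xtb_fukui_plus_C(N)H,1,0,0
xtb_fukui_plus_C(O),1,0,1
xtb_fukui_plus_C(O)H,1,1,0
xtb_fukui_zero_NH,1,1,0
xtb_fukui_zero_C(O),0,1,1
xtb_fukui_minus_C(O),1,1,0
xtb_mulliken_charge_O,0,0,1
xtb_mulliken_charge_C(N)H,1,1,0
xtb_mulliken_charge_C(O),0,0,1
xtb_mulliken_charge_C(O)H,0,1,0
jaguar_fukui_NN_HOMO_N,1,0,0
jaguar_fukui_NN_HOMO_C(N)H,0,1,0
jaguar_fukui_NN_LUMO_N,1,1,0
jaguar_fukui_NN_LUMO_NH,1,1,0
jaguar_fukui_NN_LUMO_C(N)H,1,1,0
jaguar_fukui_NN_LUMO_C(O)H,1,1,0
dipole_moment_xtb,1,1,0
C(N)_H_abstraction_energy,1,0,0
C(O)_H_abstraction_energy,1,1,0
visible_sky_O,0,1,0
visible_sky_C(N),0,0,1
visible_sky_C(O),0,0,1
homolumo_gap_xtb_deg_2,0,1,0
DSC_Sum_dH,1,1,0
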