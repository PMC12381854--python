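id,level,site,family,units,allow_missing
xtb_fukui_plus_N,atom,N,fukui_plus,e,0
xtb_fukui_plus_NH,atom,NH,fukui_plus,e,1
xtb_fukui_plus_S,atom,S,fukui_plus,e,0
xtb_fukui_plus_O,atom,O,fukui_plus,e,0
xtb_fukui_plus_C(N),atom,C(N),fukui_plus,e,0
xtb_fukui_plus_C(N)H,atom,C(N)H,fukui_plus,e,1
xtb_fukui_plus_C(O),atom,C(O),fukui_plus,e,0
xtb_fukui_plus_C(O)H,atom,C(O)H,fukui_plus,e,1
xtb_fukui_zero_N,atom,N,fukui_zero,e,0
xtb_fukui_zero_NH,atom,NH,fukui_zero,e,1
xtb_fukui_zero_S,atom,S,fukui_zero,e,0
xtb_fukui_zero_O,atom,O,fukui_zero,e,0
xtb_fukui_zero_C(N),atom,C(N),fukui_zero,e,0
xtb_fukui_zero_C(N)H,atom,C(N)H,fukui_zero,e,1
xtb_fukui_zero_C(O),atom,C(O),fukui_zero,e,0
xtb_fukui_zero_C(O)H,atom,C(O)H,fukui_zero,e,1
xtb_fukui_minus_N,atom,N,fukui_minus,e,0
xtb_fukui_minus_NH,atom,NH,fukui_minus,e,1
xtb_fukui_minus_S,atom,S,fukui_minus,e,0
xtb_fukui_minus_O,atom,O,fukui_minus,e,0
xtb_fukui_minus_C(N),atom,C(N),fukui_minus,e,0
xtb_fukui_minus_C(N)H,atom,C(N)H,fukui_minus,e,1
xtb_fukui_minus_C(O),atom,C(O),fukui_minus,e,0
xtb_fukui_minus_C(O)H,atom,C(O)H,fukui_minus,e,1
xtb_mulliken_charge_N,atom,N,partial_charge,e,0
xtb_mulliken_charge_NH,atom,NH,partial_charge,e,1
xtb_mulliken_charge_S,atom,S,partial_charge,e,0
xtb_mulliken_charge_O,atom,O,partial_charge,e,0
xtb_mulliken_charge_C(N),atom,C(N),partial_charge,e,0
xtb_mulliken_charge_C(N)H,atom,C(N)H,partial_charge,e,1
xtb_mulliken_charge_C(O),atom,C(O),partial_charge,e,0
xtb_mulliken_charge_C(O)H,atom,C(O)H,partial_charge,e,1
jaguar_fukui_NN_HOMO_N,atom,N,fukui_nn_homo,e,0
jaguar_fukui_NN_HOMO_NH,atom,NH,fukui_nn_homo,e,1
jaguar_fukui_NN_HOMO_S,atom,S,fukui_nn_homo,e,0
jaguar_fukui_NN_HOMO_O,atom,O,fukui_nn_homo,e,0
jaguar_fukui_NN_HOMO_C(N),atom,C(N),fukui_nn_homo,e,0
jaguar_fukui_NN_HOMO_C(N)H,atom,C(N)H,fukui_nn_homo,e,1
jaguar_fukui_NN_HOMO_C(O),atom,C(O),fukui_nn_homo,e,0
jaguar_fukui_NN_HOMO_C(O)H,atom,C(O)H,fukui_nn_homo,e,1
jaguar_fukui_NN_LUMO_N,atom,N,fukui_nn_lumo,e,0
jaguar_fukui_NN_LUMO_NH,atom,NH,fukui_nn_lumo,e,1
jaguar_fukui_NN_LUMO_S,atom,S,fukui_nn_lumo,e,0
jaguar_fukui_NN_LUMO_O,atom,O,fukui_nn_lumo,e,0
jaguar_fukui_NN_LUMO_C(N),atom,C(N),fukui_nn_lumo,e,0
jaguar_fukui_NN_LUMO_C(N)H,atom,C(N)H,fukui_nn_lumo,e,1
jaguar_fukui_NN_LUMO_C(O),atom,C(O),fukui_nn_lumo,e,0
jaguar_fukui_NN_LUMO_C(O)H,atom,C(O)H,fukui_nn_lumo,e,1
visible_sky_N,atom,N,visible_sky,fraction,0
visible_sky_NH,atom,NH,visible_sky,fraction,1
visible_sky_S,atom,S,visible_sky,fraction,0
visible_sky_O,atom,O,visible_sky,fraction,0
visible_sky_C(N),atom,C(N),visible_sky,fraction,0
visible_sky_C(N)H,atom,C(N)H,visible_sky,fraction,1
visible_sky_C(O),atom,C(O),visible_sky,fraction,0
visible_sky_C(O)H,atom,C(O)H,visible_sky,fraction,1
C(O)_H_abstraction_energy,bond,C(O)H,bde,kcal/mol,1
C(N)_H_abstraction_energy,bond,C(N)H,bde,kcal/mol,1
ring_C_O_bond_order,bond,C(O),bond_order,dimensionless,0
dipole_moment_xtb,molecule,none,dipole,debye,0
homolumo_gap_xtb,molecule,none,homo_lumo_gap,eV,0
labute_asa,molecule,none,labute_asa,A^2,0
dipole_moment_xtb_deg_1,degradant,none,dipole,debye,0
homolumo_gap_xtb_deg_1,degradant,none,homo_lumo_gap,eV,0
labute_asa_deg_1,degradant,none,labute_asa,A^2,0
free_energy_diff_deg_1,degradant,none,free_energy_diff,kcal/mol,0
dipole_moment_xtb_deg_2,degradant,none,dipole,debye,0
homolumo_gap_xtb_deg_2,degradant,none,homo_lumo_gap,eV,0
labute_asa_deg_2,degradant,none,labute_asa,A^2,0
free_energy_diff_deg_2,degradant,none,free_energy_diff,kcal/mol,0
DSC_Sum_dH,experimental,none,dsc_sum_dh,kcal/mol,0
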