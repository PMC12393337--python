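variant,apo_cm1,shift_cm1,holo_cm1,source
F28oCNF,2230.8,0.3,2231.1,in_cell_QCL
F62oCNF,2227.5,0.6,2228.1,in_cell_QCL
F92oCNF,2226.4,14.9,2241.3,in_cell_QCL
F96oCNF,2227.6,6.3,2233.9,in_cell_QCL
F96oCNF_C69A,2227.6,0.0,2227.6,in_cell_QCL_control
free_oCNF,2232.3,0.0,2232.3,aqueous_reference
sfGFP_Y66oCNF,2225.8,0.0,2225.8,in_cell_QCL
benzonitrile,2235.0,0.0,2235.0,aqueous_reference
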