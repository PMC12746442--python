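# Kt-7 standard-MD simulation manifest: force field, solvent model,
# ion parameters, number of independent simulations, length per simulation
# in microseconds.  Rows 1-18 are the isolated Kt-7; the last two rows are
# the L7Ae protein-RNA complex runs.
ff,solvent,ions,n_sims,length_us
OL3,OPC,Joung&Cheatham,5,10
OL3,SPC/E,Joung&Cheatham,5,10
OL3 (250 mM KCl),SPC/E,Joung&Cheatham,5,10
OL3 (2-amino-purine A_L2),SPC/E,Joung&Cheatham,5,20
OL3 (MgCl2),SPC/E,Joung&Cheatham + Li&Merz (Mg2+),5,10
OL3 (MgCl2 preequilibrated),SPC/E,Joung&Cheatham + Li&Merz (Mg2+),5,10
OL3 (A-minor I start),SPC/E,Joung&Cheatham,5,10
OL3_0BPh-CP-gHBfix21,OPC,Joung&Cheatham,5,10
OL3_R2.7,OPC,Li&Merz,5,10
PAK,OPC,Joung&Cheatham,5,10
ROC,TIP3P,Joung&Cheatham,5,10
Chen&Garcia,TIP3P,Chen&Pappu,5,10
DESRES,TIP4P-D,Charmm22,5,10
DES-Amber,TIP4P-D,Charmm22,5,10
BSFF1,TIP3P,Joung&Cheatham,5,10
CHARMM36,TIP3P_Charmm36,CHARMM,5,10
CHARMM_Drude,SWM4-NDP,CHARMM_Drude,5,2.5
AMOEBA,AMOEBA,AMOEBA,5,2.5
OL3 + L7Ae,SPC/E,Joung&Cheatham,3,10
AMOEBA + L7Ae,AMOEBA,AMOEBA,3,1
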