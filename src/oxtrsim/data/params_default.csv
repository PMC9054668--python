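name,value,scope,units,description
init_OXT,0.0,shared,nM,initial extracellular ligand (clamped by the stimulus protocol)
init_R,100.0,shared,nM,initial free receptor
init_RL,0.0,shared,nM,initial ligand-receptor complex
init_G,250.0,shared,nM,initial inactive G-protein
init_RLG,0.0,shared,nM,initial receptor/G-protein coupled complex
init_Ga,0.0,shared,nM,initial active G-alpha
init_PLC,100.0,shared,nM,initial free PLC
init_GaPLC,0.0,shared,nM,initial active G-alpha/PLC complex
init_PIP2,10000.0,shared,nM,initial PIP2 pool
init_IP3,0.0,shared,nM,initial IP3
init_Ca_cyt,100.0,shared,nM,initial cytosolic free Ca2+
init_Ca_er,150000.0,shared,nM,initial ER free Ca2+ (ER-volume concentration)
kf_bind,0.001,shared,nM-1.s-1,ligand-receptor association
kr_bind,0.05,shared,s-1,ligand-receptor dissociation
kf_coupling_wt,0.0002,wt,nM-1.s-1,receptor/G-protein coupling (WT)
kf_coupling_mut,0.00045774,mut,nM-1.s-1,receptor/G-protein coupling (A218T)
kr_coupling,0.05,shared,s-1,receptor/G-protein uncoupling
k_gact,2.0,shared,s-1,G-protein activation (GDP/GTP exchange)
k_gdeact,0.15,shared,s-1,G-alpha deactivation (GTP hydrolysis)
kf_plc,0.01,shared,nM-1.s-1,G-alpha/PLC association
kr_plc,1.0,shared,s-1,G-alpha/PLC dissociation
k_ip3prod,0.0006,shared,nM-1.s-1,IP3 production from PIP2 by active PLC
k_ip3deg,0.08,shared,s-1,IP3 degradation
k_rel,0.0048,shared,s-1,IP3R release rate (scaled by IP3 and Ca2+ Hill gates)
v_pump,970.0,shared,nM.s-1,maximal ER reuptake pump rate (Hill n=2)
k_leak,0.0018167,shared,s-1,first-order ER leak (balances the pump at 100 nM)
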