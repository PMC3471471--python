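drug,dose_mg_d,column,sbp_mmHg,dbp_mmHg,map_mmHg,pp_mmHg,hr_beat_min,co_L_min,sv_mL,ef_pct,sw_J_beat,cii,source
enalapril,20,baseline,155,101,119,54,73,5.26,72,28.35,2.95,9.85,trial-report-1
enalapril,20,simulated,143,92,109,51,73,5.48,75,32.05,2.70,4.01,model
enalapril,20,measured,137,88,,,,,,,,,trial-report-1
lisinopril,20,baseline,158,94,115,64,73,5.11,70,27.24,3.03,13.22,trial-report-2
lisinopril,20,simulated,141,90,107,51,73,5.62,77,34.53,2.48,1.80,model
lisinopril,20,measured,140,88,,,,,,,,,trial-report-2
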