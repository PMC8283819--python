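# Transcribed bench-scale bioaugmentation runs (co-metabolism primary-matrix study).
# removal_pct is the reported 21-day time-averaged removal of refractory COD; it does not
# equal the single-snapshot rate computed from the concentration columns (e.g. row 3:
# 100*(381.25-55.33)/381.25 = 85.49 while the reported average is 86.33).
# The study summary quotes a +8.36 point gain for rice-washing water over the control,
# whereas the tabulated averages differ by 93.14 - 86.33 = 6.81 points; both are recorded
# as printed, the discrepancy is not resolved here.
number,reinforcer,influent_cod_mgL,refractory_cod_mgL,effluent_cod_mgL,removal_pct,mlvss_gL,us_kg_per_kg_d,do_mgL
1,20% glucose + 0.25 mg/L Fe3+,456.33,387.01,48.36,88.01,2.6,0.55,2.1
2,20% rice washing water + 0.25 mg/L Fe3+,458.01,379.05,25.58,93.14,2.4,0.52,2.8
3,control,389.36,381.25,55.33,86.33,1.7,0.56,2.4
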