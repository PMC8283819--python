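# Transcribed removal percentages by hydrophilic/hydrophobic organic fraction from a
# bench-scale comparison of PAC-AS, AS and PAC SBR systems (published measurements).
# The AS-system TPI-A rate was printed only as "<2"; recorded here as 1.9.
system,fraction,removal_pct
AS,TPI-N,73
AS,HPI,60
AS,HPO-N,55
AS,HPO-A,49
AS,TPI-A,1.9
PAC,HPO-A,72.33
PAC,HPO-N,62.01
PAC,TPI-N,48.77
PAC,TPI-A,26.01
PAC,HPI,22.01
PAC-AS,TPI-N,82.01
PAC-AS,HPO-A,77.86
PAC-AS,HPO-N,74.33
PAC-AS,HPI,68.21
PAC-AS,TPI-A,29.04
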