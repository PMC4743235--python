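group,avg_diameter_mm,min_diameter_mm,length_mm,lambda,special
ica,5.4834,4.0,117.3925,50.0154,1
large_arteries,6.5,2.0,200.0,61.5385,0
main_artery_branches,2.4,1.2,100.0,83.3333,0
terminal_artery_branches,1.2,0.1,10.0,16.6667,0
arterioles,0.1,0.01,12.0,240.0,0
capillaries,0.008,0.004,1.0,250.0,0
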