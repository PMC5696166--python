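# Reference biodistribution summary: 64Cu-PCTA-cetuximab in SNU-1066 HNSCC
# xenograft mice (decay-corrected %ID/g, mean ± SD over n = 4 animals per
# timepoint, 3.7 MBq injected). Tumor uptake peaks at 48 h.
# nuclide: cu64
# injected_MBq: 3.7
# decay_corrected: true
organ,time_h,mean_pidg,sd,n
Tumor,2,3.9,1.3,4
Tumor,24,8.4,1.0,4
Tumor,48,12.8,1.7,4
Blood,2,30.8,4.7,4
Blood,24,13.3,1.0,4
Blood,48,11.7,1.9,4
Muscle,2,1.3,0.1,4
Muscle,24,2.5,0.2,4
Muscle,48,2.5,0.4,4
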