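# Reference biodistribution summary: 177Lu-PCTA-cetuximab in SNU-1066 HNSCC
# xenograft mice (decay-corrected %ID/g, mean ± SD over n = 4 animals per
# timepoint, 3.7 MBq injected). Tumor uptake peaks at 7 d; blood clears
# biexponentially. Used as the printed-data input for tumor dosimetry.
# nuclide: lu177
# injected_MBq: 3.7
# decay_corrected: true
organ,time_h,mean_pidg,sd,n
Tumor,2,2.5,0.6,4
Tumor,24,11.4,2.6,4
Tumor,72,17.9,5.3,4
Tumor,120,16.8,2.6,4
Tumor,168,20.6,5.2,4
Tumor,336,17.5,4.9,4
Blood,2,29.0,3.6,4
Blood,24,13.0,2.0,4
Blood,72,8.9,2.1,4
Blood,120,5.8,2.0,4
Blood,168,3.8,1.3,4
Blood,336,2.3,0.4,4
Muscle,2,1.1,0.1,4
Muscle,24,2.2,0.1,4
Muscle,72,1.4,0.2,4
Muscle,120,1.0,0.4,4
Muscle,168,0.9,0.1,4
Muscle,336,0.5,0.1,4
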