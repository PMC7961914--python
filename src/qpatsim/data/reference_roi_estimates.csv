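set_so2,approach,roi1,roi2,avg_abs_dev
8.7,none,2.7,4.9,4.9
8.7,homogeneous,5.7,7.1,2.6
8.7,ground_truth,7.3,8.5,0.8
57.6,none,39.0,27.6,24.3
57.6,homogeneous,64.1,48.4,8.0
57.6,ground_truth,71.2,52.4,9.4
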