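statistic,PC1,PC2,PC3
eigenvalue,12.550,3.576,0.662
variance_pct,69.720,19.868,3.675
cumulative_pct,69.720,89.588,93.263
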