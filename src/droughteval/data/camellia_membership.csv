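species,stage,mu1,mu2,mu3
C. reticulata,control,0.780,0.045,0.784
C. reticulata,T1,0.585,0.116,0.679
C. reticulata,T2,0.466,0.007,0.715
C. reticulata,T3,0.225,0.054,0.171
C. reticulata,T4,0.000,0.000,0.416
C. sasanqua,control,1.000,0.775,0.626
C. sasanqua,T1,0.607,0.762,0.000
C. sasanqua,T2,0.408,0.958,0.340
C. sasanqua,T3,0.293,0.870,0.562
C. sasanqua,T4,0.000,1.000,1.000
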