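site_id,reach,section,DO,TN,NH3N,TP,CODMn
T1,main,upstream,8.0,0.1,0.075,0.005,0.5
T2,main,upstream,7.0,0.35,0.325,0.0175,1.5
T3,main,midstream,6.25,0.75,0.75,0.0375,2.5
T4,main,downstream,5.75,1.25,1.25,0.075,3.5
T5,main,downstream,5.0,1.75,1.75,0.15,4.5
T6,tributary,midstream,9.0,4.54,0.25,0.09,4.51
T7,tributary,downstream,8.0,12.34,0.5,0.05,4.84
T8,tributary,downstream,6.8,1.2,0.3,0.058,3.443
T9,tributary,upstream,9.28,0.0,0.02,0.0,0.8
T10,tributary,midstream,6.625,0.55,0.5375,0.0275,2.0
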