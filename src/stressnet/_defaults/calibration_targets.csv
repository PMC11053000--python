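marker,condition,value,tolerance,weight
ros_percent,stressed,171.92,0.02,1.0
cortisol,stressed,106.7,0.02,1.0
tnfa,stressed,2.2e-3,0.02,1.0
sbp,stressed,156.1,0.05,0.5
ros_percent,combined,5.58,0.02,1.0
cortisol,combined,8.57,0.02,1.0
tnfa,combined,4.1e-5,0.02,1.0
cortisol,oxidative_only,26.0,0.10,0.3
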