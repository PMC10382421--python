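run_id,x1_coded,x2_coded,x1_actual,x2_actual,point_class,PS_mean,PS_sd,PDI_mean,PDI_sd,ZP_mean,ZP_sd
F1,0.0,0.0,2.05,50.0,center,313.4,9.67,0.44,0.02,-31.9,0.98
F2,1.0,-1.0,2.8,25.0,factorial,270.6,5.76,0.48,0.03,-33.8,1.09
F3,-1.0,-1.0,1.2999999999999998,25.0,factorial,304.2,4.61,0.37,0.05,-19.0,0.89
F4,0.0,0.0,2.05,50.0,center,324.8,5.09,0.39,0.08,-32.7,0.73
F5,0.0,1.4142135623730951,2.05,85.35533905932738,axial,416.3,2.67,0.66,0.01,-28.6,1.1
F6,1.0,1.0,2.8,75.0,factorial,276.2,3.67,0.48,0.03,-37.2,0.84
F7,0.0,0.0,2.05,50.0,center,322.4,8.6,0.41,0.09,-33.1,0.99
F8,1.4142135623730951,0.0,3.1106601717798212,50.0,axial,168.5,4.69,0.37,0.01,-39.2,0.63
F9,-1.4142135623730951,0.0,0.9893398282201784,50.0,axial,241.2,3.8,0.25,0.03,-21.6,0.63
F10,0.0,-1.4142135623730951,2.05,14.644660940672622,axial,406.3,6.29,0.53,0.03,-19.6,0.94
F11,-1.0,1.0,1.2999999999999998,75.0,factorial,311.2,3.57,0.37,0.07,-22.6,0.83
F12,0.0,0.0,2.05,50.0,center,315.7,2.54,0.45,0.04,-32.4,0.62
F13,0.0,0.0,2.05,50.0,center,306.7,1.76,0.4,0.06,-30.9,0.98
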