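substrate_id,solvent,temperature_C,pressure_bar,time_h,n_points,selected
SM1,DCE,25,5,1,192,0
SM1,DCE,25,5,16,192,0
SM1,DCE,25,30,16,192,0
SM1,Methanol,25,5,1,192,1
SM1,Methanol,25,5,16,576,0
SM1,Methanol,25,30,16,192,0
SM2,DCE,25,5,1,192,0
SM2,DCE,25,5,16,192,0
SM2,Methanol,25,5,1,192,1
SM2,Methanol,25,5,16,192,0
SM3,DCE,25,5,1,192,0
SM3,DCE,25,5,16,192,0
SM3,Methanol,25,5,1,192,1
SM3,Methanol,25,5,16,192,0
SM4,Methanol,50,5,16,192,1
SM5,Methanol,25,5,16,96,0
SM5,Methanol,50,5,16,192,1
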