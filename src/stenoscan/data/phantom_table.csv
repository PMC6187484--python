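vessel_type,stenosis_class,design_d,design_D,design_dos,cbct_d,cbct_D,cbct_dos,rus_d,rus_D,rus_dos,err_design_cbct,err_cbct_rus
A,I,9,10,19.0,8.8,9.8,20.6,8.7,9.8,21.2,1.6,0.6
A,II,7.8,10,40.2,7.5,9.8,42.6,7.3,9.7,43.4,2.4,0.7
A,III,4.5,10,80.2,4.3,10,81.5,4.2,9.8,81.6,1.3,1.0
B,I,7,8,23.0,7,7.9,21.5,7.1,8.1,23.2,1.5,1.7
B,II,6.2,8,40.0,6.2,7.9,38.4,6,7.8,40.8,1.6,2.4
B,III,3.5,8,80.9,3.3,7.8,82.2,3.1,7.9,84.6,1.3,2.4
C,I,4.5,5,19.0,4.2,4.8,23.4,3.9,4.5,24.9,4.4,1.5
C,II,3.9,5,39.2,3.6,4.8,43.3,3.5,4.7,44.5,4.1,2.2
C,III,2.2,5,80.6,1.8,4.6,84.7,1.6,4.5,87.4,4.1,2.7
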