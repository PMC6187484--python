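patient,rus_D,rus_d,rus_dos,rus_variation,doc_D,doc_d,doc_dos,doc_variation,avg_error
1,76.8,23.6,90.6,1.2,75.2,19.8,93.0,4.7,2.4
2,88.3,44.4,74.7,0.6,86.8,41.7,76.9,6.8,2.9
3,128.0,96.0,43.8,1.8,125.7,88,50.9,17.1,7.1
4,108.0,85.1,37.9,2.1,107.2,81.8,41.8,9.6,3.9
5,96.1,81.2,28.6,1.1,94.8,78.4,31.6,8.8,3.0
6,170.0,143.4,28.8,2.2,169.8,140.3,31.7,12.9,2.9
7,93.2,77.2,31.3,1.4,90.1,74.2,32.1,7.0,2.5
8,113.0,92.8,32.6,1.6,109.2,85.1,39.2,11.1,6.6
9,98.5,79.8,34.4,1.5,97.8,73.4,43.7,3.6,9.3
10,96.0,52.2,70.4,2.0,93.1,48.6,72.7,2.4,2.3
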