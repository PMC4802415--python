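# synthetic densitometry table (RhoA-GTP readout, naive arm)
# generated by racrho.population.make_dose_response_dataset(noise_cv=0.05, n_reps=3, seed=1) at the calibrated defaults
dose,arm,mean,sd,n_reps
0.0,naive,2.9920659479472143,0.041926487107823665,3
1000.0,naive,7.073052622614533,0.4059506300860574,3
2000.0,naive,16.954745367786906,0.49864569293131195,3
3000.0,naive,33.68276847506467,0.43613025241793063,3
4000.0,naive,436.35038151618255,6.270954427733153,3
5000.0,naive,515.8488792807879,11.641929383708518,3
6000.0,naive,505.1432629125091,10.11661808963149,3
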