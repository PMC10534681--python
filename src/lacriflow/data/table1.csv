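version,d_in,d_out,H_in,H_out,theta,D_t,D_b,H_b,H
1,2.05,3.61,7.44,8.70,90,12.18,-,-,43.96
2,2.61,5.34,4.30,3.00,<90,14.27,-,-,30.17
3,1.29,2.9,13.0,13.0,<90,14.37,20,9.30,28.08
4,1.26,2.95,10.8,11.5,90,14.37,20,7.15,20.14
5,2.43,5.00,10.1,5.60,<90,13.38,20,12.72,18.63
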