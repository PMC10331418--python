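cell,beta,tau_m_ms,mu,D_ms,tau_A_ms,delta_A,tau_d_ms,t_ref_ms
2012-04-20-ak,373.7,1.74,21.88,0.13,294.95,142.7,4.29,0.93
2011-10-25-ad,301.4,2.90,-34.38,0.44,116.08,60.7,4.08,0.74
2012-12-20-ab,46.6,1.35,-4.79,0.03,48.0,19.3,1.21,1.14
2012-12-20-ad,124.2,1.06,-16.21,0.06,93.17,23.0,4.54,1.09
2012-12-20-ae,190.1,1.65,-31.84,0.07,61.15,28.8,5.37,0.92
2012-12-21-ai,291.2,2.10,-54.69,0.55,127.44,36.8,3.15,1.20
2014-06-06-ac,382.9,4.98,-70.70,4.00,111.95,55.1,2.40,0.62
2018-05-08-af,266.9,1.19,-35.16,0.17,61.96,50.7,8.87,1.10
2018-06-25-ad,286.1,2.39,-29.69,2.44,96.35,62.5,1.88,1.09
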