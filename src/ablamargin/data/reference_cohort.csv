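case_id,ltp,time_months,residual_pct,u1,u2,u3,u4,u5,u6,u7,u8,u9,u10,age,male,size_mm,subcapsular,vessel,organ,prior_ctx,prior_hr,adjuvant_ctx
77,1,7.5,69.1,13.1,20.7,30.0,38.8,46.1,53.2,58.0,61.8,65.9,68.8,64,0,32,1,1,1,1,1,
58,1,14.29,0.0,0.0,0.0,16.9,28.6,42.9,47.8,51.9,55.1,57.9,60.4,49,0,10,0,1,0,1,1,
57,1,14.29,0.0,0.0,0.0,14.4,25.7,34.9,39.7,45.1,49.5,53.0,56.5,49,0,12,0,1,0,1,1,
48,1,13.34,0.0,0.0,8.0,14.7,20.1,27.1,31.7,36.4,39.2,44.4,48.7,61,1,20,0,0,0,1,1,
79,1,15.11,0.0,0.0,0.0,7.6,13.0,18.2,24.5,29.1,33.6,38.6,42.1,62,1,48,0,1,0,0,0,
13,1,13.60,5.3,7.8,10.9,16.2,19.0,21.5,24.6,28.7,31.6,34.5,38.0,31,1,40,0,0,0,0,0,
15,1,47.41,0.0,0.0,0.0,4.2,7.6,11.6,16.5,22.3,26.8,29.1,31.4,69,1,13,0,0,0,0,0,
39,1,13.34,0.0,1.3,5.1,9.2,12.3,15.0,17.1,19.2,21.2,23.5,25.1,58,1,36,1,0,0,1,1,
61,1,26.12,0.0,0.0,0.0,3.3,4.4,6.1,11.3,13.4,15.8,21.0,23.3,70,1,30,0,1,0,0,0,
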