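parameter,group1_mean,group2_mean,pct_diff_g2_vs_g1,pct_diff_s910_vs_s12_group1,pct_diff_s910_vs_s12_group2
Fmeanright,3.23378,3.32861,2.932471,-33.036,-10.7484
Fmeanleft,3.130066,3.361978,7.409167,-13.9833,-7.16814
Fstdright,1.602262,1.677908,4.721194,-44.5339,-4.89131
Fstdleft,1.636178,1.664,1.700452,-38.0757,6.912041
Fmaxright,7.440562,7.404284,-0.48757,-40.0544,-4.70138
Fmaxleft,7.207226,7.418431,2.930461,-22.9619,-0.15563
Fminright,1.115157,1.093743,-1.92032,-8.27834,-7.12886
Fminleft,1.143257,1.101681,-3.63659,54.48436,-16.6559
Fintright,292.9955,554.118,89.12169,-16.6674,-27.9686
Fintleft,264.0737,553.0317,109.4232,-7.45437,-25.5471
relative moment of Fmaxright,-0.18384,-0.10031,-45.4335,172.9532,259.3863
relative moment of Fmaxleft,-0.25515,-0.15481,-39.3265,367.6416,17.76975
relative moment of Fminright,-0.26997,-0.1258,-53.4028,-29.3991,289.4865
relative moment of Fminleft,-0.26446,-0.07727,-70.7802,220.8015,-42.983
maximal difference of consecutive extremums right,5.751664,5.336946,-7.2104,-38.65,-3.86
maximal difference of consecutive extremums left,5.4427,5.5412,1.8093,-33.601,6.1558
number of local maxima right,8.366667,10.29444,23.04117,-1.54639,0.530504
number of local maxima left,8.183333,9.933333,21.38493,1.11e-14,-2.98913
number of local minima right,8.35,10.27222,23.02063,-2.57732,0.797872
number of local minima left,8.15,9.911111,21.60873,1.052632,-2.74725
position-related task time,8.944167,9.221111,3.096369,-5.62303,-16.1943
overall duration,17.73583,18.14944,2.332065,-5.31215,-16.4159
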