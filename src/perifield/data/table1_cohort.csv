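subject_id,eye,best_vision_sphere_d,bcva_logmar,oms_db,v_tot_dbsr
1,OD,0.25,0.80,1.87,2.56
1,OS,-0.25,0.48,1.92,2.1
2,OD,-2.50,0.26,,
2,OS,-2.0,0.22,4.82,18.14
3,OD,-5.50,0.14,7.06,20.02
3,OS,-5.75,0.16,8.23,26.12
4,OD,1.25,0.08,12.81,41.06
4,OS,1.50,0.20,11.33,37.6
5,OD,-1.0,0.52,3.97,3.04
5,OS,-0.50,0.40,3.42,2.5
6,OD,0.0,0.20,3.11,5.44
6,OS,0.00,0.22,3.67,6.01
7,OD,-4.25,0.00,9.11,33.73
7,OS,-4.25,-0.04,9.30,33.87
8,OD,-2.25,0.22,7.99,22.86
8,OS,-2.00,0.22,8.36,25.87
9,OD,0.75,0.40,6.07,12.27
9,OS,0.75,0.32,5.38,10.06
10,OD,-9.00,0.42,11.14,39.13
10,OS,-8.75,0.34,11.05,38.44
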