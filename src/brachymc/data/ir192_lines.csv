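energy_MeV,intensity
8.900000e-03,4.000000e-03
9.400000e-03,2.880000e-02
1.110000e-02,1.550000e-02
6.150000e-02,1.200000e-02
6.300000e-02,2.050000e-02
6.510000e-02,2.620000e-02
6.680000e-02,4.460000e-02
7.570000e-02,1.530000e-02
7.780000e-02,4.700000e-03
1.363000e-01,1.990000e-03
2.013000e-01,4.730000e-03
2.058000e-01,3.340000e-02
2.833000e-01,2.660000e-03
2.960000e-01,2.871000e-01
3.085000e-01,2.970000e-01
3.165000e-01,8.286000e-01
3.745000e-01,7.260000e-03
4.165000e-01,6.700000e-03
4.205000e-01,6.900000e-04
4.681000e-01,4.784000e-01
4.846000e-01,3.189000e-02
4.891000e-01,4.380000e-03
5.886000e-01,4.522000e-02
5.935000e-01,4.200000e-04
6.044000e-01,8.216000e-02
6.125000e-01,5.340000e-02
8.845000e-01,2.910000e-03
1.061500e+00,5.300000e-04
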