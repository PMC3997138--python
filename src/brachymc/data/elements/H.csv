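energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,7.856810e-01,3.286294e-01,3.898562e-01,6.719533e-02,3.323638e-01
5.507508e-03,6.768811e-01,2.304389e-01,3.891073e-01,5.733488e-02,2.345356e-01
5.988401e-03,6.044625e-01,1.662224e-01,3.884012e-01,4.983886e-02,1.706599e-01
5.989599e-03,6.043143e-01,1.660927e-01,3.883995e-01,4.982204e-02,1.705310e-01
6.066528e-03,5.950697e-01,1.580240e-01,3.882868e-01,4.875892e-02,1.625165e-01
6.538346e-03,5.484898e-01,1.179763e-01,3.875978e-01,4.291573e-02,1.228001e-01
6.539654e-03,5.483812e-01,1.178842e-01,3.875959e-01,4.290100e-02,1.227090e-01
6.682290e-03,5.370919e-01,1.083653e-01,3.873883e-01,4.133833e-02,1.132897e-01
7.111289e-03,5.088835e-01,8.500455e-02,3.867654e-01,3.711354e-02,9.022732e-02
7.112711e-03,5.088022e-01,8.493823e-02,3.867634e-01,3.710061e-02,9.016199e-02
7.360553e-03,4.956619e-01,7.431176e-02,3.864048e-01,3.494541e-02,7.970696e-02
8.107660e-03,4.657481e-01,5.095946e-02,3.853290e-01,2.945965e-02,5.686738e-02
8.332167e-03,4.588732e-01,4.580741e-02,3.850073e-01,2.805852e-02,5.186822e-02
8.333833e-03,4.588251e-01,4.577168e-02,3.850049e-01,2.804849e-02,5.183362e-02
8.930600e-03,4.438688e-01,3.494557e-02,3.841531e-01,2.477005e-02,4.141125e-02
9.837070e-03,4.276086e-01,2.396400e-02,3.828688e-01,2.077579e-02,3.103569e-02
1.083555e-02,4.152864e-01,1.643337e-02,3.814671e-01,1.738593e-02,2.416261e-02
1.193537e-02,4.057268e-01,1.126922e-02,3.799387e-01,1.451892e-02,1.971090e-02
1.314683e-02,3.981036e-01,7.727895e-03,3.782737e-01,1.210199e-02,1.694025e-02
1.448125e-02,3.918320e-01,5.299422e-03,3.764620e-01,1.007063e-02,1.534399e-02
1.595112e-02,3.864948e-01,3.634091e-03,3.744927e-01,8.367997e-03,1.457564e-02
1.757019e-02,3.817914e-01,2.492086e-03,3.723550e-01,6.944399e-03,1.439840e-02
1.935359e-02,3.775031e-01,1.708954e-03,3.700374e-01,5.756686e-03,1.465061e-02
1.999800e-02,3.761144e-01,1.503910e-03,3.692094e-01,5.401032e-03,1.481280e-02
2.000200e-02,3.761059e-01,1.502736e-03,3.692043e-01,5.398927e-03,1.481390e-02
2.131801e-02,3.734682e-01,1.171919e-03,3.675287e-01,4.767644e-03,1.522195e-02
2.348182e-02,3.695663e-01,8.036461e-04,3.648173e-01,3.945387e-03,1.603707e-02
2.586526e-02,3.657058e-01,5.511022e-04,3.618919e-01,3.262747e-03,1.704439e-02
2.849062e-02,3.618162e-01,3.779196e-04,3.587416e-01,2.696691e-03,1.820830e-02
3.138246e-02,3.578427e-01,2.591592e-04,3.553557e-01,2.227782e-03,1.950380e-02
3.456783e-02,3.537419e-01,1.777190e-04,3.517245e-01,1.839678e-03,2.091282e-02
3.807652e-02,3.494797e-01,1.218712e-04,3.478392e-01,1.518683e-03,2.242157e-02
4.194134e-02,3.450290e-01,8.357348e-05,3.436921e-01,1.253351e-03,2.401879e-02
4.619845e-02,3.403686e-01,5.731071e-05,3.392771e-01,1.034139e-03,2.569443e-02
5.088767e-02,3.354825e-01,3.930095e-05,3.345901e-01,8.531046e-04,2.743885e-02
5.605284e-02,3.303595e-01,2.695072e-05,3.296289e-01,7.036511e-04,2.924215e-02
6.174229e-02,3.249924e-01,1.848152e-05,3.243936e-01,5.803044e-04,3.109386e-02
6.800923e-02,3.193783e-01,1.267374e-05,3.188871e-01,4.785281e-04,3.298266e-02
7.491227e-02,3.135182e-01,8.691047e-06,3.131149e-01,3.945664e-04,3.489633e-02
7.610339e-02,3.125389e-01,8.172187e-06,3.121483e-01,3.823355e-04,3.521008e-02
7.611861e-02,3.125264e-01,8.165812e-06,3.121361e-01,3.821829e-04,3.521406e-02
8.251598e-02,3.074169e-01,5.959906e-06,3.070856e-01,3.253117e-04,3.682177e-02
9.089148e-02,3.010831e-01,4.087019e-06,3.008108e-01,2.681931e-04,3.874509e-02
1.001171e-01,2.945288e-01,2.804757e-06,2.943049e-01,2.210819e-04,4.065186e-02
1.102791e-01,2.877696e-01,2.044579e-06,2.875853e-01,1.822106e-04,4.252741e-02
1.214726e-01,2.808236e-01,1.490434e-06,2.806720e-01,1.501038e-04,4.435677e-02
1.338023e-01,2.737119e-01,1.086479e-06,2.735873e-01,1.235213e-04,4.612546e-02
1.473834e-01,2.664577e-01,7.920089e-07,2.663555e-01,1.014184e-04,4.781960e-02
1.623431e-01,2.590857e-01,6.184674e-07,2.590022e-01,8.292201e-05,4.942625e-02
1.788212e-01,2.516217e-01,4.904024e-07,2.515539e-01,6.732303e-05,5.093352e-02
1.969718e-01,2.440919e-01,3.888555e-07,2.440374e-01,5.407418e-05,5.233091e-02
2.169647e-01,2.365223e-01,3.083359e-07,2.364793e-01,4.278313e-05,5.360942e-02
2.389870e-01,2.289385e-01,2.444893e-07,2.289051e-01,3.319134e-05,5.476152e-02
2.632445e-01,2.213646e-01,1.938633e-07,2.213392e-01,2.513744e-05,5.578121e-02
2.899643e-01,2.138228e-01,1.537203e-07,2.138042e-01,1.851171e-05,5.666387e-02
3.193961e-01,2.063337e-01,1.218897e-07,2.063203e-01,1.321317e-05,5.740618e-02
3.518153e-01,1.989151e-01,9.665020e-08,1.989059e-01,9.119938e-06,5.800594e-02
3.875250e-01,1.915827e-01,7.663700e-08,1.915766e-01,6.078586e-06,5.846192e-02
4.268594e-01,1.843498e-01,6.076791e-08,1.843459e-01,3.910619e-06,5.877369e-02
4.701863e-01,1.772275e-01,4.818479e-08,1.772250e-01,2.429421e-06,5.894155e-02
5.179109e-01,1.702247e-01,3.820725e-08,1.702232e-01,1.459091e-06,5.896642e-02
5.704797e-01,1.633487e-01,3.029574e-08,1.633479e-01,8.487036e-07,5.884980e-02
6.283843e-01,1.566056e-01,2.402245e-08,1.566051e-01,4.791728e-07,5.859378e-02
6.921662e-01,1.500001e-01,1.904816e-08,1.499999e-01,2.632607e-07,5.820109e-02
7.624222e-01,1.435362e-01,1.510389e-08,1.435361e-01,1.411231e-07,5.767511e-02
8.398092e-01,1.372173e-01,1.197635e-08,1.372172e-01,7.401146e-08,5.701996e-02
9.250511e-01,1.310463e-01,9.496427e-09,1.310463e-01,3.807398e-08,5.624054e-02
1.018945e+00,1.250261e-01,7.530017e-09,1.250261e-01,1.926025e-08,5.534258e-02
1.122370e+00,1.191593e-01,5.970789e-09,1.191593e-01,9.602682e-09,5.433261e-02
1.236292e+00,1.134486e-01,4.734427e-09,1.134486e-01,4.728448e-09,5.321798e-02
1.361777e+00,1.078965e-01,3.754077e-09,1.078965e-01,2.303773e-09,5.200681e-02
1.500000e+00,1.025056e-01,2.976727e-09,1.025056e-01,1.112394e-09,5.070784e-02
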