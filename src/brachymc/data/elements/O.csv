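energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,5.687342e+01,5.595206e+01,1.964998e-01,7.248584e-01,5.591747e+01
5.507508e-03,4.162982e+01,4.078728e+01,1.961224e-01,6.464116e-01,4.076521e+01
5.988401e-03,3.179687e+01,3.101997e+01,1.957665e-01,5.811309e-01,3.100533e+01
5.989599e-03,3.177644e+01,3.099969e+01,1.957656e-01,5.809787e-01,3.098506e+01
6.066528e-03,3.049966e+01,2.973264e+01,1.957088e-01,5.713056e-01,2.971893e+01
6.538346e-03,2.398546e+01,2.327384e+01,1.953615e-01,5.162609e-01,2.326466e+01
6.539654e-03,2.397010e+01,2.325862e+01,1.953606e-01,5.161181e-01,2.324946e+01
6.682290e-03,2.237026e+01,2.167416e+01,1.952559e-01,5.008509e-01,2.166607e+01
7.111289e-03,1.833721e+01,1.768386e+01,1.949420e-01,4.584148e-01,1.767838e+01
7.112711e-03,1.832552e+01,1.767230e+01,1.949409e-01,4.582823e-01,1.766683e+01
7.360553e-03,1.643051e+01,1.579978e+01,1.947602e-01,4.359774e-01,1.579550e+01
8.107660e-03,1.208896e+01,1.151754e+01,1.942180e-01,3.772064e-01,1.151588e+01
8.332167e-03,1.108921e+01,1.053342e+01,1.940558e-01,3.617352e-01,1.053236e+01
8.333833e-03,1.108221e+01,1.052654e+01,1.940546e-01,3.616238e-01,1.052547e+01
8.930600e-03,8.914229e+00,8.395920e+00,1.936253e-01,3.246833e-01,8.396115e+00
9.837070e-03,6.591594e+00,6.120361e+00,1.929779e-01,2.782554e-01,6.121897e+00
1.083555e-02,4.891386e+00,4.461550e+00,1.922714e-01,2.375654e-01,4.464103e+00
1.193537e-02,3.645971e+00,3.252329e+00,1.915011e-01,2.021413e-01,3.255695e+00
1.314683e-02,2.732972e+00,2.370845e+00,1.906619e-01,1.714648e-01,2.374900e+00
1.448125e-02,2.063038e+00,1.728271e+00,1.897487e-01,1.450181e-01,1.732945e+00
1.595112e-02,1.570920e+00,1.259855e+00,1.887561e-01,1.223092e-01,1.265112e+00
1.757019e-02,1.208957e+00,9.183944e-01,1.876786e-01,1.028839e-01,9.242252e-01
1.935359e-02,9.423195e-01,6.694805e-01,1.865105e-01,8.632849e-02,6.758908e-01
1.999800e-02,8.688773e-01,6.014810e-01,1.860932e-01,8.130311e-02,6.080911e-01
2.000200e-02,8.684517e-01,6.010878e-01,1.860906e-01,8.127328e-02,6.076991e-01
2.131801e-02,7.455460e-01,4.880301e-01,1.852460e-01,7.226982e-02,4.950372e-01
2.348182e-02,6.000107e-01,3.557586e-01,1.838794e-01,6.037271e-02,3.633873e-01
2.586526e-02,4.920796e-01,2.593367e-01,1.824049e-01,5.033791e-02,2.676172e-01
2.849062e-02,4.117651e-01,1.890483e-01,1.808171e-01,4.189974e-02,1.980137e-01
3.138246e-02,3.517447e-01,1.378102e-01,1.791105e-01,3.482396e-02,1.474958e-01
3.456783e-02,3.066450e-01,1.004593e-01,1.772802e-01,2.890543e-02,1.109010e-01
3.807652e-02,2.725194e-01,7.323166e-02,1.753219e-01,2.396586e-02,8.446514e-02
4.194134e-02,2.464665e-01,5.338356e-02,1.732316e-01,1.985130e-02,6.544352e-02
4.619845e-02,2.263510e-01,3.891493e-02,1.710064e-01,1.642969e-02,5.183410e-02
5.088767e-02,2.106001e-01,2.836776e-02,1.686440e-01,1.358843e-02,4.217617e-02
5.605284e-02,1.980545e-01,2.067920e-02,1.661433e-01,1.123197e-02,3.540338e-02
6.174229e-02,1.878587e-01,1.507448e-02,1.635046e-01,9.279615e-03,3.073666e-02
6.800923e-02,1.793814e-01,1.098882e-02,1.607291e-01,7.663484e-03,2.760621e-02
7.491227e-02,1.721569e-01,8.010503e-03,1.578198e-01,6.326655e-03,2.559463e-02
7.610339e-02,1.710720e-01,7.607762e-03,1.573326e-01,6.131645e-03,2.535031e-02
7.611861e-02,1.710584e-01,7.602789e-03,1.573264e-01,6.129211e-03,2.534734e-02
8.251598e-02,1.658418e-01,5.839404e-03,1.547808e-01,5.221539e-03,2.439550e-02
9.089148e-02,1.601833e-01,4.256741e-03,1.516181e-01,4.308442e-03,2.378328e-02
1.001171e-01,1.549963e-01,3.103029e-03,1.483389e-01,3.554322e-03,2.359133e-02
1.102791e-01,1.501458e-01,2.262010e-03,1.449521e-01,2.931721e-03,2.369607e-02
1.214726e-01,1.455343e-01,1.648934e-03,1.414675e-01,2.417853e-03,2.400535e-02
1.338023e-01,1.410925e-01,1.202021e-03,1.378966e-01,1.993834e-03,2.445013e-02
1.473834e-01,1.367718e-01,8.762352e-04,1.342516e-01,1.644022e-03,2.497840e-02
1.623431e-01,1.325850e-01,6.842384e-04,1.305453e-01,1.355478e-03,2.559630e-02
1.788212e-01,1.284511e-01,5.425543e-04,1.267911e-01,1.117496e-03,2.621439e-02
1.969718e-01,1.243540e-01,4.302084e-04,1.230025e-01,9.212142e-04,2.680643e-02
2.169647e-01,1.202934e-01,3.411259e-04,1.191930e-01,7.592786e-04,2.736180e-02
2.389870e-01,1.162714e-01,2.704895e-04,1.153754e-01,6.255571e-04,2.787189e-02
2.632445e-01,1.122913e-01,2.144797e-04,1.115619e-01,5.149020e-04,2.832986e-02
2.899643e-01,1.083571e-01,1.700677e-04,1.077640e-01,4.229748e-04,2.873036e-02
3.193961e-01,1.044729e-01,1.348521e-04,1.039919e-01,3.461414e-04,2.906931e-02
3.518153e-01,1.006432e-01,1.069285e-04,1.002548e-01,2.814306e-04,2.934370e-02
3.875250e-01,9.687194e-02,8.478698e-05,9.656063e-02,2.265257e-04,2.955140e-02
4.268594e-01,9.316310e-02,6.723028e-05,9.291613e-02,1.797427e-04,2.969099e-02
4.701863e-01,8.952025e-02,5.330901e-05,8.932698e-02,1.399563e-04,2.976168e-02
5.179109e-01,8.594657e-02,4.227040e-05,8.579784e-02,1.064618e-04,2.976318e-02
5.704797e-01,8.244478e-02,3.351754e-05,8.233247e-02,7.879447e-05,2.969565e-02
6.283843e-01,7.901705e-02,2.657712e-05,7.893392e-02,5.655141e-05,2.955968e-02
6.921662e-01,7.566499e-02,2.107384e-05,7.560465e-02,3.926076e-05,2.935625e-02
7.624222e-01,7.238973e-02,1.671011e-05,7.234670e-02,2.632524e-05,2.908677e-02
8.398092e-01,6.919208e-02,1.324998e-05,6.916179e-02,1.703820e-05,2.875310e-02
9.250511e-01,6.607260e-02,1.050633e-05,6.605144e-02,1.064716e-05,2.835751e-02
1.018945e+00,6.303184e-02,8.330798e-06,6.301708e-02,6.430715e-06,2.790273e-02
1.122370e+00,6.007041e-02,6.605753e-06,6.006005e-02,3.760384e-06,2.739195e-02
1.236292e+00,5.718904e-02,5.237911e-06,5.718167e-02,2.133497e-06,2.682878e-02
1.361777e+00,5.438858e-02,4.153305e-06,5.438325e-02,1.177382e-06,2.621722e-02
1.500000e+00,5.166999e-02,3.293287e-06,5.166606e-02,6.336678e-07,2.556164e-02
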