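energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,1.369184e+02,1.337996e+02,1.788266e-01,2.939925e+00,1.338014e+02
5.507508e-03,1.039666e+02,1.010629e+02,1.784831e-01,2.725166e+00,1.010648e+02
5.988401e-03,8.197251e+01,7.926254e+01,1.781592e-01,2.531812e+00,7.926457e+01
5.989599e-03,8.192604e+01,7.921654e+01,1.781584e-01,2.531344e+00,7.921858e+01
6.066528e-03,7.901542e+01,7.633587e+01,1.781067e-01,2.501449e+00,7.633793e+01
6.538346e-03,6.392343e+01,6.142087e+01,1.777907e-01,2.324766e+00,6.142308e+01
6.539654e-03,4.935839e+02,4.910818e+02,1.777898e-01,2.324293e+00,3.595069e+02
6.682290e-03,4.637212e+02,4.612703e+02,1.776946e-01,2.273208e+00,3.403210e+02
7.111289e-03,3.873565e+02,3.850529e+02,1.774089e-01,2.126188e+00,2.901799e+02
7.112711e-03,3.871325e+02,3.848294e+02,1.774079e-01,2.125717e+00,2.900305e+02
7.360553e-03,3.506340e+02,3.484114e+02,1.772434e-01,2.045340e+00,2.654740e+02
8.107660e-03,2.651652e+02,2.631656e+02,1.767500e-01,1.822777e+00,2.062942e+02
8.332167e-03,2.450455e+02,2.431074e+02,1.766024e-01,1.761492e+00,1.919865e+02
8.333833e-03,2.449039e+02,2.429663e+02,1.766013e-01,1.761047e+00,1.918854e+02
8.930600e-03,2.005632e+02,1.987770e+02,1.762106e-01,1.610011e+00,1.597797e+02
9.837070e-03,1.517286e+02,1.501422e+02,1.756215e-01,1.410699e+00,1.234020e+02
1.083555e-02,1.148093e+02,1.134070e+02,1.749785e-01,1.227403e+00,9.507174e+01
1.193537e-02,8.689551e+01,8.565971e+01,1.742774e-01,1.061525e+00,7.308818e+01
1.314683e-02,6.578829e+01,6.470136e+01,1.735137e-01,9.134106e-01,5.608229e+01
1.448125e-02,4.982615e+01,4.887090e+01,1.726827e-01,7.825734e-01,4.296226e+01
1.595112e-02,3.775341e+01,3.691366e+01,1.717794e-01,6.679674e-01,3.286381e+01
1.757019e-02,2.862104e+01,2.788200e+01,1.707988e-01,5.682344e-01,2.510693e+01
1.935359e-02,2.171175e+01,2.106012e+01,1.697358e-01,4.818973e-01,1.915936e+01
1.999800e-02,1.977492e+01,1.915015e+01,1.693559e-01,4.554218e-01,1.747835e+01
2.000200e-02,1.976365e+01,1.913903e+01,1.693536e-01,4.552643e-01,1.746854e+01
2.131801e-02,1.648342e+01,1.590734e+01,1.685850e-01,4.074868e-01,1.460632e+01
2.348182e-02,1.252625e+01,1.201530e+01,1.673413e-01,3.436106e-01,1.112572e+01
2.586526e-02,9.530502e+00,9.075517e+00,1.659994e-01,2.889850e-01,8.468280e+00
2.849062e-02,7.262009e+00,6.855012e+00,1.645544e-01,2.424421e-01,6.441604e+00
3.138246e-02,5.543727e+00,5.177798e+00,1.630013e-01,2.029282e-01,4.897531e+00
3.456783e-02,4.241781e+00,3.910947e+00,1.613357e-01,1.694978e-01,3.722218e+00
3.807652e-02,3.254917e+00,2.954057e+00,1.595534e-01,1.413068e-01,2.828347e+00
4.194134e-02,2.506545e+00,2.231288e+00,1.576512e-01,1.176062e-01,2.149050e+00
4.619845e-02,1.938721e+00,1.685359e+00,1.556260e-01,9.773583e-02,1.633198e+00
5.088767e-02,1.507597e+00,1.273003e+00,1.534761e-01,8.111813e-02,1.241738e+00
5.605284e-02,1.179989e+00,9.615375e-01,1.512004e-01,6.725112e-02,9.448811e-01
6.174229e-02,9.307789e-01,7.262783e-01,1.487990e-01,5.570166e-02,7.199214e-01
6.800923e-02,7.409514e-01,5.485799e-01,1.462731e-01,4.609836e-02,5.495696e-01
7.491227e-02,5.961091e-01,4.143590e-01,1.436255e-01,3.812465e-02,4.206701e-01
7.610339e-02,5.759555e-01,3.958143e-01,1.431821e-01,3.695917e-02,4.028482e-01
7.611861e-02,5.757056e-01,3.955846e-01,1.431765e-01,3.694462e-02,4.026274e-01
8.251598e-02,4.853497e-01,3.129779e-01,1.408598e-01,3.151201e-02,3.232193e-01
9.089148e-02,4.004169e-01,2.364016e-01,1.379816e-01,2.603373e-02,2.496148e-01
1.001171e-01,3.350174e-01,1.785209e-01,1.349973e-01,2.149915e-02,1.940422e-01
1.102791e-01,2.820084e-01,1.323449e-01,1.319151e-01,1.774841e-02,1.497484e-01
1.214726e-01,2.415046e-01,9.811273e-02,1.287439e-01,1.464792e-02,1.170432e-01
1.338023e-01,2.103155e-01,7.273502e-02,1.254942e-01,1.208624e-02,9.293972e-02
1.473834e-01,1.860691e-01,5.392147e-02,1.221770e-01,9.970617e-03,7.521485e-02
1.623431e-01,1.670022e-01,3.997421e-02,1.188040e-01,8.224005e-03,6.221424e-02
1.788212e-01,1.518045e-01,2.963453e-02,1.153875e-01,6.782456e-03,5.270708e-02
1.969718e-01,1.395020e-01,2.196930e-02,1.119397e-01,5.592974e-03,4.577782e-02
2.169647e-01,1.293712e-01,1.628675e-02,1.084728e-01,4.611678e-03,4.074566e-02
2.389870e-01,1.208748e-01,1.207404e-02,1.049985e-01,3.802258e-03,3.710445e-02
2.632445e-01,1.136137e-01,8.950983e-03,1.015281e-01,3.134677e-03,3.447809e-02
2.899643e-01,1.072915e-01,6.635733e-03,9.807173e-02,2.584067e-03,3.258722e-02
3.193961e-01,1.019722e-01,5.203462e-03,9.463891e-02,2.129787e-03,3.150701e-02
3.518153e-01,9.719920e-02,4.206679e-03,9.123790e-02,1.754619e-03,3.079295e-02
3.875250e-01,9.272091e-02,3.400842e-03,8.787596e-02,1.444100e-03,3.020185e-02
4.268594e-01,8.849466e-02,2.749372e-03,8.455925e-02,1.186041e-03,2.969748e-02
4.701863e-01,8.448585e-02,2.222698e-03,8.129291e-02,9.702445e-04,2.925082e-02
5.179109e-01,8.066649e-02,1.796915e-03,7.808118e-02,7.883934e-04,2.883865e-02
5.704797e-01,7.701421e-02,1.452695e-03,7.492748e-02,6.340305e-04,2.844256e-02
6.283843e-01,7.351150e-02,1.174415e-03,7.183460e-02,5.024890e-04,2.804803e-02
6.921662e-01,7.014488e-02,9.494425e-04,6.880477e-02,3.906687e-04,2.764381e-02
7.624222e-01,6.690403e-02,7.675659e-04,6.583984e-02,2.966316e-04,2.722130e-02
8.398092e-01,6.378099e-02,6.205299e-04,6.294138e-02,2.190848e-04,2.677422e-02
9.250511e-01,6.076932e-02,5.016603e-04,6.011078e-02,1.568783e-04,2.629818e-02
1.018945e+00,5.786353e-02,4.055616e-04,5.734932e-02,1.086475e-04,2.579044e-02
1.122370e+00,5.505879e-02,3.278716e-04,5.465825e-02,7.266799e-05,2.524966e-02
1.236292e+00,5.235073e-02,2.650641e-04,5.203875e-02,4.691380e-05,2.467572e-02
1.361777e+00,4.973555e-02,2.142880e-04,4.949202e-02,2.924414e-05,2.406947e-02
1.500000e+00,4.721008e-02,1.732387e-04,4.701922e-02,1.762124e-05,2.343267e-02
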