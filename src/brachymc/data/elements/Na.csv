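energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,1.318507e+02,1.305931e+02,1.880263e-01,1.069591e+00,1.300346e+02
5.507508e-03,9.691753e+01,9.576589e+01,1.876652e-01,9.639792e-01,9.539487e+01
5.988401e-03,7.448699e+01,7.342554e+01,1.873246e-01,8.741253e-01,7.316466e+01
5.989599e-03,7.444019e+01,7.337895e+01,1.873238e-01,8.739137e-01,7.311830e+01
6.066528e-03,7.151446e+01,7.046674e+01,1.872694e-01,8.604436e-01,7.021974e+01
6.538346e-03,5.653066e+01,5.556070e+01,1.869371e-01,7.830217e-01,5.538075e+01
6.539654e-03,5.649521e+01,5.552545e+01,1.869362e-01,7.828192e-01,5.534565e+01
6.682290e-03,5.279900e+01,5.185105e+01,1.868361e-01,7.611118e-01,5.168698e+01
7.111289e-03,4.344746e+01,4.256068e+01,1.865357e-01,7.002455e-01,4.243481e+01
7.112711e-03,4.342026e+01,4.253367e+01,1.865347e-01,7.000543e-01,4.240792e+01
7.360553e-03,3.900731e+01,3.815320e+01,1.863617e-01,6.677513e-01,3.804461e+01
8.107660e-03,2.884148e+01,2.807400e+01,1.858429e-01,5.816380e-01,2.800257e+01
8.332167e-03,2.648763e+01,2.574320e+01,1.856877e-01,5.587355e-01,2.567985e+01
8.333833e-03,2.647113e+01,2.572687e+01,1.856866e-01,5.585702e-01,2.566358e+01
8.930600e-03,2.134628e+01,2.065749e+01,1.852758e-01,5.035097e-01,2.061099e+01
9.837070e-03,1.581852e+01,1.520026e+01,1.846563e-01,4.336023e-01,1.517052e+01
1.083555e-02,1.174043e+01,1.118470e+01,1.839803e-01,3.717479e-01,1.116629e+01
1.193537e-02,8.730701e+00,8.229960e+00,1.832431e-01,3.174976e-01,8.219240e+00
1.314683e-02,6.508474e+00,6.055794e+00,1.824402e-01,2.702404e-01,6.050356e+00
1.448125e-02,4.866856e+00,4.455992e+00,1.815663e-01,2.292973e-01,4.454236e+00
1.595112e-02,3.653423e+00,3.278822e+00,1.806166e-01,1.939849e-01,3.279689e+00
1.757019e-02,2.755870e+00,2.412632e+00,1.795855e-01,1.636518e-01,2.415429e+00
1.935359e-02,2.091433e+00,1.775270e+00,1.784678e-01,1.376952e-01,1.779545e+00
1.999800e-02,1.907884e+00,1.600021e+00,1.780685e-01,1.297946e-01,1.604724e+00
2.000200e-02,1.906820e+00,1.599006e+00,1.780660e-01,1.297477e-01,1.603711e+00
2.131801e-02,1.599108e+00,1.306285e+00,1.772578e-01,1.155655e-01,1.311747e+00
2.348182e-02,1.233911e+00,9.611944e-01,1.759502e-01,9.676670e-02,9.676634e-01
2.586526e-02,9.626612e-01,7.072690e-01,1.745393e-01,8.085294e-02,7.146371e-01
2.849062e-02,7.608707e-01,5.204248e-01,1.730199e-01,6.742602e-02,5.286325e-01
3.138246e-02,6.104596e-01,3.829405e-01,1.713869e-01,5.613221e-02,3.919604e-01
3.456783e-02,4.980714e-01,2.817764e-01,1.696356e-01,4.665936e-02,2.916021e-01
3.807652e-02,4.138332e-01,2.073376e-01,1.677617e-01,3.873397e-02,2.179759e-01
4.194134e-02,3.504434e-01,1.525638e-01,1.657615e-01,3.211812e-02,1.640296e-01
4.619845e-02,3.024984e-01,1.122599e-01,1.636322e-01,2.660627e-02,1.245725e-01
5.088767e-02,2.659971e-01,8.260344e-02,1.613717e-01,2.202201e-02,9.578333e-02
5.605284e-02,2.379752e-01,6.078151e-02,1.589789e-01,1.821478e-02,7.484865e-02
6.174229e-02,2.162352e-01,4.472443e-02,1.564539e-01,1.505683e-02,5.969645e-02
6.800923e-02,1.991476e-01,3.290927e-02,1.537982e-01,1.244018e-02,4.880020e-02
7.491227e-02,1.855037e-01,2.421540e-02,1.510143e-01,1.027399e-02,4.103465e-02
7.610339e-02,1.835390e-01,2.303308e-02,1.505481e-01,9.957861e-03,4.000435e-02
7.611861e-02,1.835146e-01,2.301847e-02,1.505422e-01,9.953916e-03,3.999166e-02
8.251598e-02,1.744067e-01,1.781825e-02,1.481064e-01,8.482042e-03,3.556975e-02
9.089148e-02,1.651917e-01,1.311107e-02,1.450800e-01,7.000611e-03,3.179264e-02
1.001171e-01,1.573651e-01,9.646337e-03,1.419423e-01,5.776528e-03,2.924917e-02
1.102791e-01,1.504988e-01,7.031875e-03,1.387014e-01,4.765528e-03,2.754035e-02
1.214726e-01,1.444240e-01,5.126015e-03,1.353672e-01,3.930821e-03,2.651751e-02
1.338023e-01,1.389288e-01,3.736703e-03,1.319502e-01,3.241872e-03,2.598173e-02
1.473834e-01,1.338597e-01,2.723938e-03,1.284624e-01,2.673371e-03,2.578639e-02
1.623431e-01,1.292473e-01,2.127081e-03,1.249159e-01,2.204355e-03,2.596461e-02
1.788212e-01,1.248277e-01,1.686630e-03,1.213236e-01,1.817480e-03,2.625126e-02
1.969718e-01,1.205342e-01,1.337382e-03,1.176984e-01,1.498395e-03,2.657607e-02
2.169647e-01,1.163488e-01,1.060453e-03,1.140532e-01,1.235223e-03,2.691584e-02
2.389870e-01,1.122591e-01,8.408664e-04,1.104002e-01,1.018114e-03,2.725197e-02
2.632445e-01,1.082568e-01,6.667495e-04,1.067512e-01,8.388547e-04,2.756969e-02
2.899643e-01,1.043363e-01,5.286868e-04,1.031170e-01,6.905581e-04,2.785737e-02
3.193961e-01,1.004942e-01,4.192125e-04,9.950760e-02,5.674191e-04,2.810594e-02
3.518153e-01,9.672861e-02,3.324068e-04,9.593164e-02,4.645688e-04,2.830841e-02
3.875250e-01,9.303833e-02,2.635759e-04,9.239674e-02,3.780134e-04,2.845951e-02
4.268594e-01,8.942302e-02,2.089977e-04,8.890940e-02,3.046208e-04,2.855531e-02
4.701863e-01,8.588284e-02,1.657209e-04,8.547502e-02,2.420968e-04,2.859300e-02
5.179109e-01,8.241836e-02,1.314053e-04,8.209806e-02,1.888954e-04,2.857069e-02
5.704797e-01,7.903037e-02,1.041954e-04,7.878213e-02,1.440451e-04,2.848724e-02
6.283843e-01,7.571966e-02,8.261986e-05,7.553013e-02,1.069146e-04,2.834219e-02
6.921662e-01,7.248691e-02,6.551190e-05,7.234443e-02,7.697467e-05,2.813569e-02
7.624222e-01,6.933253e-02,5.194646e-05,6.922696e-02,5.361844e-05,2.786845e-02
8.398092e-01,6.625666e-02,4.118999e-05,6.617939e-02,3.607665e-05,2.754172e-02
9.250511e-01,6.325927e-02,3.266084e-05,6.320317e-02,2.343063e-05,2.715728e-02
1.018945e+00,6.034025e-02,2.589782e-05,6.029966e-02,1.469173e-05,2.671743e-02
1.122370e+00,5.749958e-02,2.053520e-05,5.747014e-02,8.902653e-06,2.622497e-02
1.236292e+00,5.473739e-02,1.628301e-05,5.471588e-02,5.221933e-06,2.568314e-02
1.361777e+00,5.205402e-02,1.291131e-05,5.203813e-02,2.971192e-06,2.509562e-02
1.500000e+00,4.945000e-02,1.023779e-05,4.943812e-02,1.643939e-06,2.446646e-02
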