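energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,4.449390e+02,4.428500e+02,1.884507e-01,1.900541e+00,4.217590e+02
5.507508e-03,3.293254e+02,3.273985e+02,1.880887e-01,1.738784e+00,3.132435e+02
5.988401e-03,2.556037e+02,2.538191e+02,1.877473e-01,1.596885e+00,2.437273e+02
5.989599e-03,2.554491e+02,2.536648e+02,1.877465e-01,1.596546e+00,2.435811e+02
6.066528e-03,2.457719e+02,2.440093e+02,1.876920e-01,1.574919e+00,2.344326e+02
6.538346e-03,1.959459e+02,1.943097e+02,1.873590e-01,1.448778e+00,1.872346e+02
6.539654e-03,1.958274e+02,1.941916e+02,1.873581e-01,1.448444e+00,1.871222e+02
6.682290e-03,1.834592e+02,1.818595e+02,1.872577e-01,1.412502e+00,1.753806e+02
7.111289e-03,1.520065e+02,1.505092e+02,1.869566e-01,1.310360e+00,1.454714e+02
7.112711e-03,1.519147e+02,1.504177e+02,1.869556e-01,1.310035e+00,1.453839e+02
7.360553e-03,1.369812e+02,1.355394e+02,1.867823e-01,1.254997e+00,1.311567e+02
8.107660e-03,1.023089e+02,1.010172e+02,1.862623e-01,1.105456e+00,9.805283e+01
8.332167e-03,9.421695e+01,9.296585e+01,1.861068e-01,1.064994e+00,9.031164e+01
8.333833e-03,9.416013e+01,9.290933e+01,1.861056e-01,1.064701e+00,9.025727e+01
8.930600e-03,7.643979e+01,7.528785e+01,1.856939e-01,9.662524e-01,7.328330e+01
9.837070e-03,5.713586e+01,5.611184e+01,1.850730e-01,8.389483e-01,5.475683e+01
1.083555e-02,4.272869e+01,4.182001e+01,1.843955e-01,7.242841e-01,4.090461e+01
1.193537e-02,3.197430e+01,3.116835e+01,1.836567e-01,6.222906e-01,3.055052e+01
1.314683e-02,2.394501e+01,2.322969e+01,1.828519e-01,5.324659e-01,2.281335e+01
1.448125e-02,1.794898e+01,1.731303e+01,1.819761e-01,4.539684e-01,1.703317e+01
1.595112e-02,1.347017e+01,1.290336e+01,1.810242e-01,3.857838e-01,1.271600e+01
1.757019e-02,1.012368e+01,9.616840e+00,1.799908e-01,3.268477e-01,9.492247e+00
1.935359e-02,7.622398e+00,7.167406e+00,1.788706e-01,2.761214e-01,7.085466e+00
1.999800e-02,6.927016e+00,6.487924e+00,1.784703e-01,2.606224e-01,6.417095e+00
2.000200e-02,6.922977e+00,6.483979e+00,1.784678e-01,2.605302e-01,6.413214e+00
2.131801e-02,5.752139e+00,5.341850e+00,1.776579e-01,2.326317e-01,5.288966e+00
2.348182e-02,4.353100e+00,3.981267e+00,1.763472e-01,1.954856e-01,3.948253e+00
2.586526e-02,3.306035e+00,2.967228e+00,1.749332e-01,1.638737e-01,2.947881e+00
2.849062e-02,2.521945e+00,2.211468e+00,1.734103e-01,1.370670e-01,2.201601e+00
3.138246e-02,1.934387e+00,1.648201e+00,1.717736e-01,1.144124e-01,1.644996e+00
3.456783e-02,1.493747e+00,1.228400e+00,1.700184e-01,9.532805e-02,1.229960e+00
3.807652e-02,1.162963e+00,9.155236e-01,1.681403e-01,7.929869e-02,9.205768e-01
4.194134e-02,9.143443e-01,6.823374e-01,1.661356e-01,6.587131e-02,6.900329e-01
4.619845e-02,7.271962e-01,5.085443e-01,1.640015e-01,5.465037e-02,5.183154e-01
5.088767e-02,5.860457e-01,3.790168e-01,1.617359e-01,4.529301e-02,3.904876e-01
5.605284e-02,4.793219e-01,2.824803e-01,1.593377e-01,3.750399e-02,2.954023e-01
6.174229e-02,3.983695e-01,2.105318e-01,1.568070e-01,3.103068e-02,2.247411e-01
6.800923e-02,3.367122e-01,1.569088e-01,1.541452e-01,2.565809e-02,1.722966e-01
7.491227e-02,2.895030e-01,1.169438e-01,1.513551e-01,2.120417e-02,1.334362e-01
7.610339e-02,2.829080e-01,1.114664e-01,1.508878e-01,2.055369e-02,1.281337e-01
7.611861e-02,2.828261e-01,1.113987e-01,1.508819e-01,2.054558e-02,1.280681e-01
8.251598e-02,2.531139e-01,8.715788e-02,1.484406e-01,1.751540e-02,1.047025e-01
9.089148e-02,2.248288e-01,6.495855e-02,1.454074e-01,1.446284e-02,8.351517e-02
1.001171e-01,2.026015e-01,4.840046e-02,1.422626e-01,1.193849e-02,6.793447e-02
1.102791e-01,1.841490e-01,3.528241e-02,1.390144e-01,9.852131e-03,5.576234e-02
1.214726e-01,1.695210e-01,2.571976e-02,1.356727e-01,8.128601e-03,4.711001e-02
1.338023e-01,1.577023e-01,1.874889e-02,1.322480e-01,6.705364e-03,4.101135e-02
1.473834e-01,1.479501e-01,1.366735e-02,1.287523e-01,5.530488e-03,3.676016e-02
1.623431e-01,1.404313e-01,1.067262e-02,1.251978e-01,4.560897e-03,3.454857e-02
1.788212e-01,1.338209e-01,8.462658e-03,1.215974e-01,3.760904e-03,3.307165e-02
1.969718e-01,1.277753e-01,6.710309e-03,1.179640e-01,3.100965e-03,3.199799e-02
2.169647e-01,1.221880e-01,5.320816e-03,1.143105e-01,2.556637e-03,3.122882e-02
2.389870e-01,1.169760e-01,4.219044e-03,1.106493e-01,2.107701e-03,3.068562e-02
2.632445e-01,1.120749e-01,3.345413e-03,1.069921e-01,1.737403e-03,3.030609e-02
2.899643e-01,1.074342e-01,2.652684e-03,1.033497e-01,1.431821e-03,3.004090e-02
3.193961e-01,1.030149e-01,2.103397e-03,9.973216e-02,1.179313e-03,2.985106e-02
3.518153e-01,9.878606e-02,1.667850e-03,9.614813e-02,9.700861e-04,2.970588e-02
3.875250e-01,9.472363e-02,1.322491e-03,9.260525e-02,7.958902e-04,2.958126e-02
4.268594e-01,9.080855e-02,1.048645e-03,8.911004e-02,6.498660e-04,2.945835e-02
4.701863e-01,8.702591e-02,8.315038e-04,8.566791e-02,5.264946e-04,2.932252e-02
5.179109e-01,8.336424e-02,6.593257e-04,8.228333e-02,4.215816e-04,2.916249e-02
5.704797e-01,7.981489e-02,5.228002e-04,7.895991e-02,3.321774e-04,2.896968e-02
6.283843e-01,7.637149e-02,4.145448e-04,7.570058e-02,2.563727e-04,2.873774e-02
6.921662e-01,7.302937e-02,3.287057e-04,7.250769e-02,1.929736e-04,2.846212e-02
7.624222e-01,6.978495e-02,2.606411e-04,6.938319e-02,1.411236e-04,2.813984e-02
8.398092e-01,6.663538e-02,2.066706e-04,6.632874e-02,9.996938e-05,2.776920e-02
9.250511e-01,6.357813e-02,1.638757e-04,6.334580e-02,6.845163e-05,2.734967e-02
1.018945e+00,6.061093e-02,1.299422e-04,6.043574e-02,4.525289e-05,2.688168e-02
1.122370e+00,5.773174e-02,1.030353e-04,5.759983e-02,2.887695e-05,2.636658e-02
1.236292e+00,5.493886e-02,8.169993e-05,5.483936e-02,1.779759e-05,2.580646e-02
1.361777e+00,5.223096e-02,6.478246e-05,5.215557e-02,1.060842e-05,2.520408e-02
1.500000e+00,4.960718e-02,5.136806e-05,4.954969e-02,6.126936e-06,2.456277e-02
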