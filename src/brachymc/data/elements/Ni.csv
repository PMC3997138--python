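energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,2.122900e+02,2.085559e+02,1.874721e-01,3.546619e+00,2.085577e+02
5.507508e-03,1.610155e+02,1.575286e+02,1.871120e-01,3.299791e+00,1.575306e+02
5.988401e-03,1.268107e+02,1.235480e+02,1.867725e-01,3.075943e+00,1.235501e+02
5.989599e-03,1.267384e+02,1.234763e+02,1.867716e-01,3.075399e+00,1.234784e+02
6.066528e-03,1.222135e+02,1.189861e+02,1.867175e-01,3.040649e+00,1.189883e+02
6.538346e-03,9.875871e+01,9.573783e+01,1.863861e-01,2.834488e+00,9.574015e+01
6.539654e-03,9.870259e+01,9.568227e+01,1.863852e-01,2.833933e+00,9.568459e+01
6.682290e-03,9.283416e+01,8.987381e+01,1.862854e-01,2.774071e+00,8.987617e+01
7.111289e-03,7.781076e+01,7.502362e+01,1.859859e-01,2.601151e+00,7.502613e+01
7.112711e-03,7.776666e+01,7.498008e+01,1.859849e-01,2.600595e+00,7.498259e+01
7.360553e-03,7.057586e+01,6.788440e+01,1.858124e-01,2.505651e+00,6.788700e+01
8.107660e-03,5.370166e+01,5.127514e+01,1.852951e-01,2.241227e+00,5.127798e+01
8.332167e-03,4.972015e+01,4.736699e+01,1.851404e-01,2.168021e+00,4.736990e+01
8.333833e-03,3.810686e+02,3.787160e+02,1.851393e-01,2.167488e+00,2.449622e+02
8.930600e-03,3.120084e+02,3.098373e+02,1.847297e-01,1.986339e+00,2.077230e+02
9.837070e-03,2.359593e+02,2.340295e+02,1.841120e-01,1.745711e+00,1.640081e+02
1.083555e-02,1.784758e+02,1.767695e+02,1.834380e-01,1.522876e+00,1.287553e+02
1.193537e-02,1.350221e+02,1.335194e+02,1.827030e-01,1.320008e+00,1.005962e+02
1.314683e-02,1.021711e+02,1.008512e+02,1.819024e-01,1.137971e+00,7.827653e+01
1.448125e-02,7.733353e+01,7.617596e+01,1.810312e-01,9.765382e-01,6.069767e+01
1.595112e-02,5.855279e+01,5.753800e+01,1.800842e-01,8.347024e-01,4.692606e+01
1.757019e-02,4.435023e+01,4.346019e+01,1.790562e-01,7.109801e-01,3.618540e+01
1.935359e-02,3.360841e+01,3.282680e+01,1.779418e-01,6.036698e-01,2.784057e+01
1.999800e-02,3.059795e+01,2.984968e+01,1.775436e-01,5.707249e-01,2.546269e+01
2.000200e-02,3.058043e+01,2.983236e+01,1.775411e-01,5.705287e-01,2.544880e+01
2.131801e-02,2.548283e+01,2.479507e+01,1.767354e-01,5.110297e-01,2.137836e+01
2.348182e-02,1.933528e+01,1.872847e+01,1.754315e-01,4.313833e-01,1.638823e+01
2.586526e-02,1.468337e+01,1.414618e+01,1.740248e-01,3.631713e-01,1.254432e+01
2.849062e-02,1.116251e+01,1.068503e+01,1.725099e-01,3.049692e-01,9.589731e+00
3.138246e-02,8.497098e+00,8.070729e+00,1.708817e-01,2.554881e-01,7.323024e+00
3.456783e-02,6.478770e+00,6.096065e+00,1.691356e-01,2.135691e-01,5.586968e+00
3.807652e-02,4.949985e+00,4.604542e+00,1.672672e-01,1.781755e-01,4.259326e+00
4.194134e-02,3.791608e+00,3.477950e+00,1.652729e-01,1.483851e-01,3.245382e+00
4.619845e-02,2.913533e+00,2.627000e+00,1.631499e-01,1.233829e-01,2.471958e+00
5.088767e-02,2.247603e+00,1.984253e+00,1.608960e-01,1.024539e-01,1.882658e+00
5.605284e-02,1.742251e+00,1.498766e+00,1.585103e-01,8.497473e-02,1.434113e+00
6.174229e-02,1.358462e+00,1.132063e+00,1.559928e-01,7.040638e-02,1.093039e+00
6.800923e-02,1.066712e+00,8.550816e-01,1.533448e-01,5.828540e-02,8.339288e-01
7.491227e-02,8.446540e-01,6.458689e-01,1.505691e-01,4.821589e-02,6.372687e-01
7.610339e-02,8.138110e-01,6.169629e-01,1.501044e-01,4.674366e-02,6.100289e-01
7.611861e-02,8.134286e-01,6.166049e-01,1.500984e-01,4.672529e-02,6.096914e-01
8.251598e-02,6.753756e-01,4.878443e-01,1.476698e-01,3.986144e-02,4.881465e-01
9.089148e-02,5.460735e-01,3.684835e-01,1.446524e-01,3.293753e-02,3.751804e-01
1.001171e-01,4.469922e-01,2.782638e-01,1.415239e-01,2.720449e-02,2.896301e-01
1.102791e-01,3.670422e-01,2.062884e-01,1.382926e-01,2.246120e-02,2.212319e-01
1.214726e-01,3.064376e-01,1.529301e-01,1.349682e-01,1.853935e-02,1.705538e-01
1.338023e-01,2.602332e-01,1.133734e-01,1.315613e-01,1.529843e-02,1.330595e-01
1.473834e-01,2.247535e-01,8.404838e-02,1.280837e-01,1.262144e-02,1.053647e-01
1.623431e-01,1.972673e-01,6.230853e-02,1.245477e-01,1.041108e-02,8.494639e-02
1.788212e-01,1.757445e-01,4.619189e-02,1.209660e-01,8.586591e-03,6.992399e-02
1.969718e-01,1.586764e-01,3.424395e-02,1.173515e-01,7.080994e-03,5.889668e-02
2.169647e-01,1.449422e-01,2.538645e-02,1.137170e-01,5.838819e-03,5.082134e-02
2.389870e-01,1.337089e-01,1.882003e-02,1.100748e-01,4.814157e-03,4.492157e-02
2.632445e-01,1.243576e-01,1.395206e-02,1.064365e-01,3.969026e-03,4.061976e-02
2.899643e-01,1.164283e-01,1.034324e-02,1.028131e-01,3.271997e-03,3.748641e-02
3.193961e-01,1.100220e-01,8.110731e-03,9.921430e-02,2.697018e-03,3.564113e-02
3.518153e-01,1.044283e-01,6.557028e-03,9.564887e-02,2.222403e-03,3.439574e-02
3.875250e-01,9.925534e-02,5.300954e-03,9.212440e-02,1.829987e-03,3.337353e-02
4.268594e-01,9.443730e-02,4.285496e-03,8.864733e-02,1.504468e-03,3.251872e-02
4.701863e-01,8.992063e-02,3.464560e-03,8.522308e-02,1.232984e-03,3.178637e-02
5.179109e-01,8.566187e-02,2.800884e-03,8.185607e-02,1.004913e-03,3.114043e-02
5.704797e-01,8.162608e-02,2.264343e-03,7.854991e-02,8.118207e-04,3.055205e-02
6.283843e-01,7.778551e-02,1.830582e-03,7.530750e-02,6.474274e-04,2.999829e-02
6.921662e-01,7.411852e-02,1.479913e-03,7.213119e-02,5.074191e-04,2.946106e-02
7.624222e-01,7.060839e-02,1.196419e-03,6.902291e-02,3.890551e-04,2.892631e-02
8.398092e-01,6.724215e-02,9.672313e-04,6.598433e-02,2.905962e-04,2.838331e-02
9.250511e-01,6.400952e-02,7.819471e-04,6.301688e-02,2.106885e-04,2.782413e-02
1.018945e+00,6.090194e-02,6.321562e-04,6.012192e-02,1.478633e-04,2.724319e-02
1.122370e+00,5.791207e-02,5.110595e-04,5.730074e-02,1.002645e-04,2.663691e-02
1.236292e+00,5.503340e-02,4.131602e-04,5.455460e-02,6.563136e-05,2.600337e-02
1.361777e+00,5.226024e-02,3.340147e-04,5.188475e-02,4.147218e-05,2.534207e-02
1.500000e+00,4.958775e-02,2.700304e-04,4.929240e-02,2.531855e-05,2.465364e-02
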