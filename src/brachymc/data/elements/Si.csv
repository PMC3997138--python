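energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,2.690183e+02,2.672878e+02,1.958929e-01,1.534606e+00,2.630132e+02
5.507508e-03,1.984807e+02,1.968906e+02,1.955166e-01,1.394594e+00,1.940328e+02
5.988401e-03,1.533577e+02,1.518891e+02,1.951618e-01,1.273428e+00,1.498623e+02
5.989599e-03,1.532633e+02,1.517950e+02,1.951609e-01,1.273140e+00,1.497699e+02
6.066528e-03,1.473570e+02,1.459071e+02,1.951043e-01,1.254809e+00,1.439854e+02
6.538346e-03,1.170197e+02,1.156764e+02,1.947581e-01,1.148598e+00,1.142635e+02
6.539654e-03,1.169478e+02,1.156047e+02,1.947571e-01,1.148318e+00,1.141930e+02
6.682290e-03,1.094384e+02,1.081255e+02,1.946528e-01,1.118275e+00,1.068335e+02
7.111289e-03,9.038571e+01,8.915795e+01,1.943398e-01,1.033421e+00,8.815762e+01
7.112711e-03,9.033019e+01,8.910269e+01,1.943388e-01,1.033153e+00,8.810318e+01
7.360553e-03,8.130901e+01,8.012710e+01,1.941586e-01,9.877496e-01,7.925897e+01
8.107660e-03,6.043783e+01,5.937873e+01,1.936181e-01,8.654758e-01,5.879582e+01
8.332167e-03,5.558418e+01,5.455806e+01,1.934564e-01,8.326584e-01,5.403730e+01
8.333833e-03,5.555012e+01,5.452425e+01,1.934552e-01,8.324210e-01,5.400392e+01
8.930600e-03,4.494907e+01,4.400301e+01,1.930272e-01,7.530263e-01,4.361210e+01
9.837070e-03,3.345237e+01,3.260873e+01,1.923818e-01,6.512612e-01,3.234711e+01
1.083555e-02,2.491699e+01,2.416492e+01,1.916775e-01,5.603926e-01,2.399040e+01
1.193537e-02,1.857861e+01,1.790758e+01,1.909095e-01,4.801233e-01,1.779180e+01
1.314683e-02,1.387042e+01,1.327053e+01,1.900730e-01,4.098116e-01,1.319441e+01
1.448125e-02,1.037201e+01,9.834218e+00,1.891626e-01,3.486242e-01,9.784940e+00
1.595112e-02,7.771543e+00,7.287714e+00,1.881731e-01,2.956552e-01,7.256663e+00
1.757019e-02,5.837712e+00,5.400610e+00,1.870989e-01,2.500032e-01,5.382004e+00
1.935359e-02,4.398907e+00,4.002159e+00,1.859344e-01,2.108140e-01,3.992119e+00
1.999800e-02,4.000129e+00,3.615750e+00,1.855184e-01,1.988607e-01,3.607973e+00
2.000200e-02,3.997814e+00,3.613509e+00,1.855158e-01,1.987897e-01,3.605745e+00
2.131801e-02,3.327801e+00,2.965827e+00,1.846738e-01,1.773001e-01,2.961757e+00
2.348182e-02,2.529903e+00,2.197846e+00,1.833114e-01,1.487451e-01,2.198013e+00
2.586526e-02,1.935073e+00,1.628729e+00,1.818415e-01,1.245024e-01,1.631979e+00
2.849062e-02,1.491231e+00,1.206981e+00,1.802586e-01,1.039921e-01,1.212551e+00
3.138246e-02,1.159694e+00,8.944411e-01,1.785572e-01,8.669612e-02,9.018311e-01
3.456783e-02,9.117194e-01,6.628317e-01,1.767327e-01,7.215514e-02,6.717166e-01
3.807652e-02,7.259404e-01,4.911959e-01,1.747804e-01,5.996412e-02,5.013690e-01
4.194134e-02,5.864693e-01,3.640041e-01,1.726965e-01,4.976867e-02,3.753366e-01
4.619845e-02,4.814866e-01,2.697477e-01,1.704781e-01,4.126083e-02,2.821626e-01
5.088767e-02,4.021963e-01,1.998983e-01,1.681230e-01,3.417487e-02,2.133517e-01
5.605284e-02,3.420491e-01,1.481360e-01,1.656301e-01,2.828294e-02,1.626045e-01
6.174229e-02,2.961675e-01,1.097772e-01,1.629995e-01,2.339080e-02,1.252496e-01
6.800923e-02,2.609175e-01,8.135114e-02,1.602327e-01,1.933372e-02,9.782204e-02
7.491227e-02,2.335907e-01,6.028582e-02,1.573323e-01,1.597261e-02,7.775159e-02
7.610339e-02,2.297373e-01,5.740872e-02,1.568466e-01,1.548191e-02,7.503644e-02
7.611861e-02,2.296894e-01,5.737314e-02,1.568404e-01,1.547579e-02,7.500291e-02
8.251598e-02,2.121684e-01,4.467521e-02,1.543027e-01,1.319049e-02,6.313091e-02
9.089148e-02,1.951460e-01,3.310687e-02,1.511498e-01,1.088928e-02,5.254410e-02
1.001171e-01,1.813970e-01,2.452919e-02,1.478808e-01,8.987021e-03,4.493471e-02
1.102791e-01,1.698007e-01,1.788100e-02,1.445043e-01,7.415338e-03,3.923595e-02
1.214726e-01,1.601826e-01,1.303469e-02,1.410306e-01,6.117331e-03,3.531350e-02
1.338023e-01,1.520183e-01,9.501874e-03,1.374707e-01,5.045723e-03,3.267252e-02
1.473834e-01,1.449247e-01,6.926566e-03,1.338369e-01,4.161281e-03,3.095054e-02
1.623431e-01,1.389824e-01,5.408847e-03,1.301420e-01,3.431491e-03,3.024131e-02
1.788212e-01,1.335177e-01,4.288846e-03,1.263994e-01,2.829431e-03,2.987948e-02
1.969718e-01,1.283562e-01,3.400761e-03,1.226226e-01,2.332823e-03,2.969414e-02
2.169647e-01,1.234446e-01,2.696571e-03,1.188248e-01,1.923238e-03,2.963279e-02
2.389870e-01,1.187426e-01,2.138197e-03,1.150190e-01,1.585419e-03,2.965363e-02
2.632445e-01,1.142195e-01,1.695444e-03,1.112173e-01,1.306702e-03,2.972347e-02
2.899643e-01,1.098521e-01,1.344371e-03,1.074312e-01,1.076523e-03,2.981608e-02
3.193961e-01,1.056227e-01,1.065994e-03,1.036707e-01,8.860090e-04,2.991082e-02
3.518153e-01,1.015181e-01,8.452606e-04,9.994516e-02,7.276821e-04,2.999153e-02
3.875250e-01,9.752789e-02,6.702339e-04,9.626237e-02,5.952850e-04,3.004569e-02
4.268594e-01,9.364429e-02,5.314497e-04,9.262913e-02,4.837150e-04,3.006361e-02
4.701863e-01,8.986148e-02,4.214033e-04,8.905106e-02,3.890102e-04,3.003794e-02
5.179109e-01,8.617527e-02,3.341440e-04,8.553282e-02,3.083068e-04,2.996320e-02
5.704797e-01,8.258281e-02,2.649533e-04,8.207816e-02,2.397024e-04,2.983543e-02
6.283843e-01,7.908220e-02,2.100899e-04,7.869010e-02,1.820078e-04,2.965194e-02
6.921662e-01,7.567214e-02,1.665869e-04,7.537112e-02,1.344296e-04,2.941113e-02
7.624222e-01,7.235159e-02,1.320920e-04,7.212323e-02,9.626238e-05,2.911235e-02
8.398092e-01,6.911957e-02,1.047399e-04,6.894816e-02,6.666918e-05,2.875581e-02
9.250511e-01,6.597507e-02,8.305162e-05,6.584742e-02,4.459236e-05,2.834248e-02
1.018945e+00,6.291708e-02,6.585426e-05,6.282243e-02,2.878922e-05,2.787409e-02
1.122370e+00,5.994470e-02,5.221792e-05,5.987453e-02,1.794651e-05,2.735297e-02
1.236292e+00,5.705726e-02,4.140524e-05,5.700504e-02,1.081406e-05,2.678209e-02
1.361777e+00,5.425441e-02,3.283153e-05,5.421527e-02,6.309651e-06,2.616493e-02
1.500000e+00,5.153608e-02,2.603316e-05,5.150648e-02,3.572572e-06,2.550544e-02
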