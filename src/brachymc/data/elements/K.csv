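energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,6.151522e+02,6.127398e+02,1.909695e-01,2.221344e+00,5.588874e+02
5.507508e-03,4.561701e+02,4.539395e+02,1.906027e-01,2.040078e+00,4.177208e+02
5.988401e-03,3.549889e+02,3.529188e+02,1.902568e-01,1.879842e+00,3.270223e+02
5.989599e-03,3.547764e+02,3.527067e+02,1.902559e-01,1.879458e+00,3.268309e+02
6.066528e-03,3.414728e+02,3.394277e+02,1.902008e-01,1.854934e+00,3.148420e+02
6.538346e-03,2.728800e+02,2.709788e+02,1.898633e-01,1.711344e+00,2.527682e+02
6.539654e-03,2.727167e+02,2.708159e+02,1.898623e-01,1.710962e+00,2.526198e+02
6.682290e-03,2.556625e+02,2.538029e+02,1.897606e-01,1.669876e+00,2.371142e+02
7.111289e-03,2.122350e+02,2.104929e+02,1.894555e-01,1.552690e+00,1.974877e+02
7.112711e-03,2.121081e+02,2.103663e+02,1.894545e-01,1.552317e+00,1.973715e+02
7.360553e-03,1.914562e+02,1.897780e+02,1.892788e-01,1.488913e+00,1.784501e+02
8.107660e-03,1.434086e+02,1.419042e+02,1.887519e-01,1.315720e+00,1.342155e+02
8.332167e-03,1.321719e+02,1.307147e+02,1.885943e-01,1.268630e+00,1.238235e+02
8.333833e-03,1.320930e+02,1.306361e+02,1.885931e-01,1.268289e+00,1.237505e+02
8.930600e-03,1.074486e+02,1.061071e+02,1.881759e-01,1.153309e+00,1.008890e+02
9.837070e-03,8.053163e+01,7.934028e+01,1.875468e-01,1.003810e+00,7.579935e+01
1.083555e-02,6.038099e+01,5.932572e+01,1.868601e-01,8.684085e-01,5.692345e+01
1.193537e-02,4.529362e+01,4.436008e+01,1.861114e-01,7.474277e-01,4.273090e+01
1.314683e-02,3.399550e+01,3.316970e+01,1.852959e-01,6.405043e-01,3.206547e+01
1.448125e-02,2.553346e+01,2.480224e+01,1.844084e-01,5.468079e-01,2.405450e+01
1.595112e-02,1.919426e+01,1.854557e+01,1.834438e-01,4.652454e-01,1.804000e+01
1.757019e-02,1.444424e+01,1.386722e+01,1.823966e-01,3.946201e-01,1.352622e+01
1.935359e-02,1.088404e+01,1.036905e+01,1.812614e-01,3.337373e-01,1.013994e+01
1.999800e-02,9.892415e+00,9.396443e+00,1.808558e-01,3.151161e-01,9.196476e+00
2.000200e-02,9.886652e+00,9.390794e+00,1.808533e-01,3.150053e-01,9.190993e+00
2.131801e-02,8.214822e+00,7.753327e+00,1.800325e-01,2.814629e-01,7.600380e+00
2.348182e-02,6.212909e+00,5.797455e+00,1.787043e-01,2.367498e-01,5.696420e+00
2.586526e-02,4.710892e+00,4.334976e+00,1.772713e-01,1.986453e-01,4.269403e+00
2.849062e-02,3.583442e+00,3.241425e+00,1.757282e-01,1.662893e-01,3.200162e+00
3.138246e-02,2.736715e+00,2.423736e+00,1.740696e-01,1.389097e-01,2.399223e+00
3.456783e-02,2.100427e+00,1.812319e+00,1.722909e-01,1.158173e-01,1.799436e+00
3.807652e-02,1.621927e+00,1.355139e+00,1.703876e-01,9.640012e-02,1.350422e+00
4.194134e-02,1.261763e+00,1.013289e+00,1.683562e-01,8.011867e-02,1.014396e+00
4.619845e-02,9.903683e-01,7.576741e-01,1.661936e-01,6.650065e-02,7.630251e-01
5.088767e-02,7.855747e-01,5.665415e-01,1.638976e-01,5.513553e-02,5.750706e-01
5.605284e-02,6.307608e-01,4.236245e-01,1.614674e-01,4.566892e-02,4.346142e-01
6.174229e-02,5.134598e-01,3.167600e-01,1.589029e-01,3.779684e-02,3.297276e-01
6.800923e-02,4.243191e-01,2.368534e-01,1.562056e-01,3.126012e-02,2.514732e-01
7.491227e-02,3.563212e-01,1.771042e-01,1.533781e-01,2.583885e-02,1.931549e-01
7.610339e-02,3.468508e-01,1.688992e-01,1.529046e-01,2.504693e-02,1.851674e-01
7.611861e-02,3.467333e-01,1.687977e-01,1.528986e-01,2.503704e-02,1.850686e-01
8.251598e-02,3.041995e-01,1.324275e-01,1.504247e-01,2.134734e-02,1.497563e-01
9.089148e-02,2.640014e-01,9.902105e-02,1.473510e-01,1.762939e-02,1.175194e-01
1.001171e-01,2.327371e-01,7.401899e-02,1.441641e-01,1.455402e-02,9.360587e-02
1.102791e-01,2.068418e-01,5.395751e-02,1.408725e-01,1.201172e-02,7.457337e-02
1.214726e-01,1.867306e-01,3.933332e-02,1.374861e-01,9.911179e-03,6.091828e-02
1.338023e-01,1.708648e-01,2.867275e-02,1.340157e-01,8.176369e-03,5.117241e-02
1.473834e-01,1.581188e-01,2.090153e-02,1.304732e-01,6.744119e-03,4.426306e-02
1.623431e-01,1.487549e-01,1.632167e-02,1.268712e-01,5.562008e-03,4.048844e-02
1.788212e-01,1.407512e-01,1.294197e-02,1.232227e-01,4.586589e-03,3.785951e-02
1.969718e-01,1.335847e-01,1.026210e-02,1.195407e-01,3.781882e-03,3.587310e-02
2.169647e-01,1.270937e-01,8.137143e-03,1.158384e-01,3.118116e-03,3.438087e-02
2.389870e-01,1.211511e-01,6.452198e-03,1.121283e-01,2.570664e-03,3.326493e-02
2.632445e-01,1.156574e-01,5.116152e-03,1.084221e-01,2.119136e-03,3.243172e-02
2.899643e-01,1.105345e-01,4.056759e-03,1.047311e-01,1.746616e-03,3.180711e-02
3.193961e-01,1.057209e-01,3.216732e-03,1.010652e-01,1.438993e-03,3.133244e-02
3.518153e-01,1.011683e-01,2.550649e-03,9.743325e-02,1.184420e-03,3.096140e-02
3.875250e-01,9.683843e-02,2.022490e-03,9.384303e-02,9.729147e-04,3.065750e-02
4.268594e-01,9.270091e-02,1.603696e-03,9.030109e-02,7.961147e-04,3.039207e-02
4.701863e-01,8.873177e-02,1.271622e-03,8.681296e-02,6.471893e-04,3.014269e-02
5.179109e-01,8.491227e-02,1.008309e-03,8.338314e-02,5.208172e-04,2.989190e-02
5.704797e-01,8.122796e-02,7.995202e-04,8.001530e-02,4.131360e-04,2.962623e-02
6.283843e-01,7.766793e-02,6.339648e-04,7.671240e-02,3.215684e-04,2.933544e-02
6.921662e-01,7.422402e-02,5.026908e-04,7.347683e-02,2.445012e-04,2.901194e-02
7.624222e-01,7.089004e-02,3.985994e-04,7.031057e-02,1.808676e-04,2.865029e-02
8.398092e-01,6.766110e-02,3.160621e-04,6.721530e-02,1.297371e-04,2.824689e-02
9.250511e-01,6.453312e-02,2.506156e-04,6.419249e-02,9.001608e-05,2.779970e-02
1.018945e+00,6.150257e-02,1.987211e-04,6.124353e-02,6.032068e-05,2.730797e-02
1.122370e+00,5.856631e-02,1.575722e-04,5.836972e-02,3.901655e-05,2.677212e-02
1.236292e+00,5.572166e-02,1.249440e-04,5.557235e-02,2.436664e-05,2.619351e-02
1.361777e+00,5.296647e-02,9.907204e-05,5.285269e-02,1.470850e-05,2.557437e-02
1.500000e+00,5.029913e-02,7.855736e-05,5.021197e-02,8.596142e-06,2.491757e-02
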