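energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,7.290296e+02,7.263985e+02,1.961051e-01,2.435054e+00,6.432090e+02
5.507508e-03,5.410934e+02,5.386574e+02,1.957284e-01,2.240276e+00,4.826539e+02
5.988401e-03,4.215933e+02,4.193305e+02,1.953732e-01,2.067494e+00,3.792351e+02
5.989599e-03,4.213421e+02,4.190797e+02,1.953724e-01,2.067079e+00,3.790163e+02
6.066528e-03,4.056180e+02,4.033821e+02,1.953157e-01,2.040584e+00,3.653085e+02
6.538346e-03,3.244927e+02,3.224125e+02,1.949691e-01,1.885180e+00,2.941780e+02
6.539654e-03,3.242994e+02,3.222197e+02,1.949682e-01,1.884766e+00,2.940077e+02
6.682290e-03,3.041141e+02,3.020790e+02,1.948637e-01,1.840212e+00,2.761953e+02
7.111289e-03,2.526817e+02,2.507742e+02,1.945504e-01,1.712923e+00,2.305835e+02
7.112711e-03,2.525313e+02,2.506242e+02,1.945494e-01,1.712518e+00,2.304496e+02
7.360553e-03,2.280545e+02,2.262167e+02,1.943690e-01,1.643514e+00,2.086204e+02
8.107660e-03,1.710543e+02,1.694059e+02,1.938279e-01,1.454557e+00,1.574441e+02
8.332167e-03,1.577111e+02,1.561144e+02,1.936660e-01,1.403062e+00,1.453884e+02
8.333833e-03,1.576173e+02,1.560210e+02,1.936648e-01,1.402688e+00,1.453036e+02
8.930600e-03,1.283323e+02,1.268623e+02,1.932364e-01,1.276743e+00,1.187312e+02
9.837070e-03,9.630797e+01,9.500283e+01,1.925903e-01,1.112552e+00,8.947615e+01
1.083555e-02,7.229970e+01,7.114437e+01,1.918852e-01,9.634465e-01,6.738847e+01
1.193537e-02,5.429863e+01,5.327758e+01,1.911164e-01,8.299272e-01,5.072571e+01
1.314683e-02,4.079976e+01,3.989776e+01,1.902789e-01,7.117160e-01,3.816459e+01
1.448125e-02,3.067542e+01,2.987807e+01,1.893676e-01,6.079878e-01,2.870166e+01
1.595112e-02,2.308064e+01,2.237466e+01,1.883770e-01,5.175967e-01,2.157694e+01
1.757019e-02,1.738218e+01,1.675562e+01,1.873017e-01,4.392593e-01,1.621553e+01
1.935359e-02,1.310552e+01,1.254771e+01,1.861359e-01,3.716778e-01,1.218296e+01
1.999800e-02,1.191328e+01,1.137656e+01,1.857194e-01,3.509980e-01,1.105750e+01
2.000200e-02,1.190635e+01,1.136976e+01,1.857168e-01,3.508750e-01,1.105095e+01
2.131801e-02,9.895037e+00,9.396551e+00,1.848739e-01,3.136118e-01,9.151215e+00
2.348182e-02,7.484178e+00,7.036756e+00,1.835101e-01,2.639121e-01,6.872820e+00
2.586526e-02,5.673155e+00,5.269585e+00,1.820386e-01,2.215305e-01,5.161219e+00
2.849062e-02,4.312186e+00,3.946212e+00,1.804539e-01,1.855201e-01,3.875867e+00
3.138246e-02,3.288964e+00,2.955183e+00,1.787507e-01,1.550298e-01,2.910941e+00
3.456783e-02,2.519259e+00,2.213036e+00,1.769242e-01,1.292992e-01,2.186806e+00
3.807652e-02,1.939889e+00,1.657267e+00,1.749698e-01,1.076523e-01,1.643560e+00
4.194134e-02,1.503447e+00,1.241070e+00,1.728837e-01,8.949277e-02,1.236166e+00
4.619845e-02,1.174355e+00,9.293951e-01,1.706629e-01,7.429747e-02,9.307713e-01
5.088767e-02,9.259088e-01,6.959922e-01,1.683052e-01,6.161131e-02,7.019429e-01
5.605284e-02,7.380553e-01,5.212048e-01,1.658096e-01,5.104092e-02,5.305760e-01
6.174229e-02,5.957371e-01,3.903124e-01,1.631762e-01,4.224855e-02,4.023240e-01
6.800923e-02,4.876438e-01,2.922916e-01,1.604063e-01,3.494590e-02,3.064151e-01
7.491227e-02,4.052782e-01,2.188872e-01,1.575028e-01,2.888819e-02,2.347632e-01
7.610339e-02,3.938176e-01,2.087978e-01,1.570166e-01,2.800320e-02,2.249340e-01
7.611861e-02,3.936755e-01,2.086729e-01,1.570104e-01,2.799216e-02,2.248123e-01
8.251598e-02,3.422556e-01,1.639171e-01,1.544699e-01,2.386854e-02,1.812987e-01
9.089148e-02,2.937783e-01,1.227519e-01,1.513136e-01,1.971280e-02,1.414660e-01
1.001171e-01,2.562106e-01,9.189476e-02,1.480410e-01,1.627489e-02,1.118164e-01
1.102791e-01,2.250819e-01,6.698837e-02,1.446609e-01,1.343262e-02,8.803161e-02
1.214726e-01,2.010998e-01,4.883241e-02,1.411834e-01,1.108402e-02,7.091376e-02
1.338023e-01,1.823612e-01,3.559728e-02,1.376197e-01,9.144217e-03,5.864638e-02
1.473834e-01,1.674738e-01,2.594929e-02,1.339819e-01,7.542629e-03,4.990225e-02
1.623431e-01,1.567671e-01,2.026340e-02,1.302830e-01,6.220692e-03,4.505396e-02
1.788212e-01,1.477337e-01,1.606749e-02,1.265364e-01,5.129851e-03,4.163632e-02
1.969718e-01,1.397258e-01,1.274042e-02,1.227555e-01,4.229894e-03,3.902664e-02
2.169647e-01,1.325434e-01,1.010228e-02,1.189536e-01,3.487542e-03,3.704203e-02
2.389870e-01,1.260293e-01,8.010420e-03,1.151436e-01,2.875266e-03,3.553719e-02
2.632445e-01,1.200599e-01,6.351715e-03,1.113379e-01,2.370283e-03,3.439681e-02
2.899643e-01,1.145378e-01,5.036476e-03,1.075476e-01,1.953696e-03,3.352946e-02
3.193961e-01,1.093864e-01,3.993581e-03,1.037831e-01,1.609762e-03,3.286277e-02
3.518153e-01,1.045454e-01,3.166637e-03,1.000535e-01,1.325281e-03,3.233953e-02
3.875250e-01,9.996674e-02,2.510926e-03,9.636668e-02,1.089129e-03,3.191464e-02
4.268594e-01,9.561246e-02,1.990993e-03,9.272950e-02,8.919685e-04,3.155258e-02
4.701863e-01,9.145241e-02,1.578721e-03,8.914756e-02,7.261253e-04,3.122550e-02
5.179109e-01,8.746288e-02,1.251818e-03,8.562550e-02,5.855606e-04,3.091165e-02
5.704797e-01,8.362553e-02,9.926062e-04,8.216710e-02,4.658293e-04,3.059417e-02
6.283843e-01,7.992636e-02,7.870688e-04,7.877537e-02,3.639210e-04,3.026013e-02
6.921662e-01,7.635482e-02,6.240918e-04,7.545279e-02,2.779385e-04,2.989983e-02
7.624222e-01,7.290291e-02,4.948621e-04,7.220138e-02,2.066586e-04,2.950617e-02
8.398092e-01,6.956434e-02,3.923918e-04,6.902287e-02,1.490775e-04,2.907425e-02
9.250511e-01,6.633397e-02,3.111399e-04,6.591878e-02,1.040598e-04,2.860101e-02
1.018945e+00,6.320739e-02,2.467127e-04,6.289051e-02,7.016676e-05,2.808494e-02
1.122370e+00,6.018071e-02,1.956263e-04,5.993941e-02,4.567014e-05,2.752586e-02
1.236292e+00,5.725063e-02,1.551183e-04,5.706682e-02,2.869782e-05,2.692471e-02
1.361777e+00,5.441444e-02,1.229982e-04,5.427402e-02,1.742561e-05,2.628336e-02
1.500000e+00,5.167006e-02,9.752915e-05,5.156229e-02,1.024100e-05,2.560450e-02
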