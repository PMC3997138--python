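energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,1.733671e+02,1.719333e+02,1.940218e-01,1.239770e+00,1.707640e+02
5.507508e-03,1.276006e+02,1.262863e+02,1.936491e-01,1.120684e+00,1.255073e+02
5.988401e-03,9.825279e+01,9.704075e+01,1.932977e-01,1.018742e+00,9.649102e+01
5.989599e-03,9.819150e+01,9.697970e+01,1.932969e-01,1.018501e+00,9.643042e+01
6.066528e-03,9.435869e+01,9.316228e+01,1.932408e-01,1.003169e+00,9.264146e+01
6.538346e-03,7.470875e+01,7.360106e+01,1.928979e-01,9.147901e-01,7.322005e+01
6.539654e-03,7.466221e+01,7.355475e+01,1.928969e-01,9.145583e-01,7.317406e+01
6.682290e-03,6.980897e+01,6.872647e+01,1.927936e-01,8.897011e-01,6.837862e+01
7.111289e-03,5.751769e+01,5.650538e+01,1.924836e-01,8.198235e-01,5.623734e+01
7.112711e-03,5.748192e+01,5.646983e+01,1.924826e-01,8.196035e-01,5.620202e+01
7.360553e-03,5.167472e+01,5.070001e+01,1.923041e-01,7.824111e-01,5.046808e+01
8.107660e-03,3.827643e+01,3.740175e+01,1.917688e-01,6.829116e-01,3.724757e+01
8.332167e-03,3.516930e+01,3.432133e+01,1.916086e-01,6.563652e-01,3.418404e+01
8.333833e-03,3.514752e+01,3.429973e+01,1.916075e-01,6.561734e-01,3.416257e+01
8.930600e-03,2.837494e+01,2.759154e+01,1.911836e-01,5.922143e-01,2.748952e+01
9.837070e-03,2.105576e+01,2.035447e+01,1.905444e-01,5.107453e-01,2.028752e+01
1.083555e-02,1.564392e+01,1.501564e+01,1.898468e-01,4.384379e-01,1.497229e+01
1.193537e-02,1.164110e+01,1.107714e+01,1.890861e-01,3.748668e-01,1.104973e+01
1.314683e-02,8.679331e+00,8.171687e+00,1.882575e-01,3.193864e-01,8.155101e+00
1.448125e-02,6.486913e+00,6.028311e+00,1.873559e-01,2.712460e-01,6.019131e+00
1.595112e-02,4.863176e+00,4.447128e+00,1.863758e-01,2.296726e-01,4.443077e+00
1.757019e-02,3.659909e+00,3.280678e+00,1.853119e-01,1.939192e-01,3.280244e+00
1.935359e-02,2.767627e+00,2.420179e+00,1.841585e-01,1.632896e-01,2.422361e+00
1.999800e-02,2.520863e+00,2.183157e+00,1.837464e-01,1.539597e-01,2.186062e+00
2.000200e-02,2.519432e+00,2.181783e+00,1.837439e-01,1.539042e-01,2.184693e+00
2.131801e-02,2.105441e+00,1.785383e+00,1.829100e-01,1.371472e-01,1.789523e+00
2.348182e-02,1.613566e+00,1.317090e+00,1.815606e-01,1.149158e-01,1.322761e+00
2.586526e-02,1.247808e+00,9.716266e-01,1.801047e-01,9.607683e-02,9.785554e-01
2.849062e-02,9.754790e-01,7.167758e-01,1.785369e-01,8.016639e-02,7.247926e-01
3.138246e-02,7.723939e-01,5.287706e-01,1.768518e-01,6.677156e-02,5.377743e-01
3.456783e-02,6.206497e-01,3.900778e-01,1.750446e-01,5.552728e-02,4.000128e-01
3.807652e-02,5.069871e-01,2.877631e-01,1.731110e-01,4.611297e-02,2.986037e-01
4.194134e-02,4.215812e-01,2.122849e-01,1.710471e-01,3.824917e-02,2.240245e-01
4.619845e-02,3.571479e-01,1.566041e-01,1.688499e-01,3.169394e-02,1.692476e-01
5.088767e-02,3.082844e-01,1.155279e-01,1.665173e-01,2.623924e-02,1.290867e-01
5.605284e-02,2.709812e-01,8.522578e-02,1.640482e-01,2.170725e-02,9.971368e-02
6.174229e-02,2.422612e-01,6.287166e-02,1.614427e-01,1.794680e-02,7.830243e-02
6.800923e-02,2.199131e-01,4.638087e-02,1.587022e-01,1.483000e-02,6.276599e-02
7.491227e-02,2.022942e-01,3.421550e-02,1.558296e-01,1.224910e-02,5.156266e-02
7.610339e-02,1.997795e-01,3.255851e-02,1.553485e-01,1.187241e-02,5.006306e-02
7.611861e-02,1.997482e-01,3.253802e-02,1.553424e-01,1.186770e-02,5.004457e-02
8.251598e-02,1.881836e-01,2.524101e-02,1.528290e-01,1.011365e-02,4.355292e-02
9.089148e-02,1.766745e-01,1.862047e-02,1.497061e-01,8.347933e-03,3.789394e-02
1.001171e-01,1.670915e-01,1.373447e-02,1.464683e-01,6.888731e-03,3.395983e-02
1.102791e-01,1.588195e-01,1.001200e-02,1.431241e-01,5.683394e-03,3.117273e-02
1.214726e-01,1.516701e-01,7.298430e-03,1.396835e-01,4.688135e-03,2.937091e-02
1.338023e-01,1.453446e-01,5.320325e-03,1.361577e-01,3.866602e-03,2.827393e-02
1.473834e-01,1.396256e-01,3.878349e-03,1.325586e-01,3.188648e-03,2.767569e-02
1.623431e-01,1.345568e-01,3.028542e-03,1.288990e-01,2.629302e-03,2.762582e-02
1.788212e-01,1.297615e-01,2.401427e-03,1.251922e-01,2.167895e-03,2.774908e-02
1.969718e-01,1.251429e-01,1.904167e-03,1.214514e-01,1.787329e-03,2.794745e-02
2.169647e-01,1.206732e-01,1.509874e-03,1.176899e-01,1.473454e-03,2.818957e-02
2.389870e-01,1.163322e-01,1.197227e-03,1.139204e-01,1.214545e-03,2.845039e-02
2.632445e-01,1.121053e-01,9.493193e-04,1.101551e-01,1.000847e-03,2.871003e-02
2.899643e-01,1.079820e-01,7.527453e-04,1.064051e-01,8.241914e-04,2.895279e-02
3.193961e-01,1.039551e-01,5.968756e-04,1.026805e-01,6.776995e-04,2.916639e-02
3.518153e-01,1.000194e-01,4.732815e-04,9.899056e-02,5.555858e-04,2.934132e-02
3.875250e-01,9.617129e-02,3.752799e-04,9.534294e-02,4.530619e-04,2.947027e-02
4.268594e-01,9.240829e-02,2.975713e-04,9.174440e-02,3.663119e-04,2.954774e-02
4.701863e-01,8.872895e-02,2.359537e-04,8.820052e-02,2.924764e-04,2.956967e-02
5.179109e-01,8.513255e-02,1.870951e-04,8.471588e-02,2.295790e-04,2.953320e-02
5.704797e-01,8.161892e-02,1.483537e-04,8.129421e-02,1.763575e-04,2.943643e-02
6.283843e-01,7.818817e-02,1.176343e-04,7.793852e-02,1.320157e-04,2.927830e-02
6.921662e-01,7.484046e-02,9.327597e-05,7.465123e-02,9.594897e-05,2.905851e-02
7.624222e-01,7.157584e-02,7.396146e-05,7.143437e-02,6.751553e-05,2.877743e-02
8.398092e-01,6.839417e-02,5.864639e-05,6.828962e-02,4.590734e-05,2.843607e-02
9.250511e-01,6.529513e-02,4.650257e-05,6.521850e-02,3.013383e-05,2.803603e-02
1.018945e+00,6.227837e-02,3.687336e-05,6.222240e-02,1.909386e-05,2.757951e-02
1.122370e+00,5.934358e-02,2.923806e-05,5.930266e-02,1.168774e-05,2.706923e-02
1.236292e+00,5.649068e-02,2.318378e-05,5.646058e-02,6.921410e-06,2.650846e-02
1.361777e+00,5.371980e-02,1.838315e-05,5.369744e-02,3.973297e-06,2.590089e-02
1.500000e+00,5.103132e-02,1.457658e-05,5.101453e-02,2.216315e-06,2.525062e-02
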