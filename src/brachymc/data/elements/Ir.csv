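energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,2.440071e+03,2.430060e+03,1.574215e-01,9.852706e+00,2.430062e+03
5.507508e-03,1.881382e+03,1.871791e+03,1.571191e-01,9.433631e+00,1.871792e+03
5.988401e-03,1.502316e+03,1.493127e+03,1.568339e-01,9.032238e+00,1.493129e+03
5.989599e-03,1.501509e+03,1.492321e+03,1.568332e-01,9.031237e+00,1.492323e+03
6.066528e-03,1.450899e+03,1.441775e+03,1.567877e-01,8.966958e+00,1.441777e+03
6.538346e-03,1.186534e+03,1.177803e+03,1.565095e-01,8.573984e+00,1.177805e+03
6.539654e-03,1.185897e+03,1.177167e+03,1.565088e-01,8.572900e+00,1.177169e+03
6.682290e-03,1.119160e+03,1.110549e+03,1.564249e-01,8.454875e+00,1.110551e+03
7.111289e-03,9.470651e+02,9.388055e+02,1.561734e-01,8.103375e+00,9.388076e+02
7.112711e-03,9.465571e+02,9.382987e+02,1.561726e-01,8.102220e+00,9.383008e+02
7.360553e-03,8.634753e+02,8.554171e+02,1.560278e-01,7.902161e+00,8.554193e+02
8.107660e-03,6.663699e+02,6.588979e+02,1.555934e-01,7.316359e+00,6.589003e+02
8.332167e-03,6.193555e+02,6.120538e+02,1.554635e-01,7.146195e+00,6.120563e+02
8.333833e-03,6.190238e+02,6.117234e+02,1.554625e-01,7.144943e+00,6.117259e+02
8.930600e-03,5.143888e+02,5.075261e+02,1.551186e-01,6.707626e+00,5.075287e+02
9.837070e-03,3.971724e+02,3.909296e+02,1.546000e-01,6.088190e+00,3.909325e+02
1.083555e-02,3.067449e+02,3.011194e+02,1.540340e-01,5.471410e+00,3.011226e+02
1.193537e-02,2.369658e+02,2.319418e+02,1.534168e-01,4.870573e+00,2.319452e+02
1.314683e-02,1.831071e+02,1.786567e+02,1.527445e-01,4.297643e+00,1.786604e+02
1.448125e-02,1.415272e+02,1.376130e+02,1.520129e-01,3.762200e+00,1.376170e+02
1.595112e-02,1.094205e+02,1.059985e+02,1.512178e-01,3.270810e+00,1.060029e+02
1.757019e-02,8.462419e+01,8.164693e+01,1.503546e-01,2.826901e+00,8.165174e+01
1.935359e-02,6.547030e+01,6.288978e+01,1.494187e-01,2.431100e+00,6.289501e+01
1.999800e-02,6.002361e+01,5.756684e+01,1.490844e-01,2.307685e+00,5.757221e+01
2.000200e-02,5.999179e+01,5.753576e+01,1.490823e-01,2.306947e+00,5.754113e+01
2.131801e-02,5.067207e+01,4.844180e+01,1.484057e-01,2.081866e+00,4.844748e+01
2.348182e-02,3.923657e+01,3.731303e+01,1.473109e-01,1.776227e+00,3.731918e+01
2.586526e-02,3.039749e+01,2.874092e+01,1.461297e-01,1.510437e+00,2.874758e+01
2.849062e-02,2.356347e+01,2.213813e+01,1.448576e-01,1.280478e+00,2.214533e+01
3.138246e-02,1.827810e+01,1.705223e+01,1.434904e-01,1.082385e+00,1.706000e+01
3.456783e-02,1.418918e+01,1.313474e+01,1.420241e-01,9.124157e-01,1.314311e+01
3.807652e-02,1.102481e+01,1.011723e+01,1.404552e-01,7.671268e-01,1.012623e+01
4.194134e-02,8.575119e+00,7.792948e+00,1.387807e-01,6.433903e-01,7.802613e+00
4.619845e-02,6.678020e+00,6.002636e+00,1.369979e-01,5.383859e-01,6.012988e+00
5.088767e-02,5.208310e+00,4.623621e+00,1.351054e-01,4.495839e-01,4.634685e+00
5.605284e-02,4.069244e+00,3.561414e+00,1.331020e-01,3.747279e-01,3.573211e+00
6.174229e-02,3.186038e+00,2.743233e+00,1.309881e-01,3.118175e-01,2.755781e+00
6.800923e-02,2.500872e+00,2.113016e+00,1.287646e-01,2.590908e-01,2.126329e+00
7.491227e-02,1.969024e+00,1.627583e+00,1.264338e-01,2.150075e-01,1.641670e+00
7.610339e-02,1.894299e+00,1.559715e+00,1.260435e-01,2.085402e-01,1.573930e+00
7.611861e-02,8.596586e+00,8.262088e+00,1.260385e-01,2.084594e-01,1.390873e+00
8.251598e-02,6.986147e+00,6.683918e+00,1.239992e-01,1.782303e-01,1.560416e+00
9.089148e-02,5.454069e+00,5.184998e+00,1.214655e-01,1.476062e-01,1.581899e+00
1.001171e-01,4.263208e+00,4.022222e+00,1.188384e-01,1.221471e-01,1.490105e+00
1.102791e-01,3.337344e+00,3.120208e+00,1.161251e-01,1.010115e-01,1.342553e+00
1.214726e-01,2.617297e+00,2.420477e+00,1.133336e-01,8.348598e-02,1.174365e+00
1.338023e-01,2.057108e+00,1.877667e+00,1.104728e-01,6.896852e-02,1.006092e+00
1.473834e-01,1.621091e+00,1.456585e+00,1.075527e-01,5.695298e-02,8.489638e-01
1.623431e-01,1.281534e+00,1.129935e+00,1.045834e-01,4.701526e-02,7.083712e-01
1.788212e-01,1.016915e+00,8.765383e-01,1.015758e-01,3.880091e-02,5.861593e-01
1.969718e-01,8.105230e-01,6.799678e-01,9.854074e-02,3.201444e-02,4.821125e-01
2.169647e-01,6.493786e-01,5.274798e-01,9.548882e-02,2.640996e-02,3.949039e-01
2.389870e-01,5.234020e-01,4.091884e-01,9.243042e-02,2.178319e-02,3.226878e-01
2.632445e-01,4.247648e-01,3.174247e-01,8.937537e-02,1.796465e-02,2.634572e-01
2.899643e-01,3.473865e-01,2.462398e-01,8.633276e-02,1.481390e-02,2.152504e-01
3.193961e-01,2.871969e-01,1.916714e-01,8.331083e-02,1.221466e-02,1.767836e-01
3.518153e-01,2.398600e-01,1.494723e-01,8.031692e-02,1.007071e-02,1.459435e-01
3.875250e-01,2.022239e-01,1.165640e-01,7.735740e-02,8.302469e-03,1.210897e-01
4.268594e-01,1.721826e-01,9.090088e-02,7.443769e-02,6.844026e-03,1.011245e-01
4.701863e-01,1.480908e-01,7.088783e-02,7.156232e-02,5.640652e-03,8.512416e-02
5.179109e-01,1.292807e-01,5.589900e-02,6.873503e-02,4.646653e-03,7.286256e-02
5.704797e-01,1.147264e-01,4.494397e-02,6.595883e-02,3.823625e-03,6.370951e-02
6.283843e-01,1.025112e-01,3.613589e-02,6.323615e-02,3.139206e-03,5.614775e-02
6.921662e-01,9.218936e-02,2.905401e-02,6.056898e-02,2.566369e-03,4.989250e-02
7.624222e-01,8.340216e-02,2.336003e-02,5.795895e-02,2.083179e-03,4.470525e-02
8.398092e-01,7.586212e-02,1.878195e-02,5.540743e-02,1.672734e-03,4.038754e-02
9.250511e-01,6.933967e-02,1.510108e-02,5.291565e-02,1.322937e-03,3.677509e-02
1.018945e+00,6.365215e-02,1.214159e-02,5.048473e-02,1.025832e-03,3.373268e-02
1.122370e+00,5.865432e-02,9.762089e-03,4.811577e-02,7.764547e-04,3.114950e-02
1.236292e+00,5.423016e-02,7.848924e-03,4.580982e-02,5.714129e-04,2.893527e-02
1.361777e+00,5.028619e-02,6.310699e-03,4.356793e-02,4.075599e-04,2.701674e-02
1.500000e+00,4.674614e-02,5.073934e-03,4.139112e-02,2.810861e-04,2.533486e-02
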