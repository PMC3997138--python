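energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,1.603750e+02,1.570339e+02,1.829591e-01,3.158126e+00,1.570357e+02
5.507508e-03,1.217263e+02,1.186125e+02,1.826077e-01,2.931223e+00,1.186144e+02
5.988401e-03,9.593516e+01,9.302647e+01,1.822763e-01,2.726416e+00,9.302856e+01
5.989599e-03,9.588068e+01,9.297249e+01,1.822755e-01,2.725919e+00,9.297457e+01
6.066528e-03,9.246802e+01,8.959159e+01,1.822226e-01,2.694210e+00,8.959369e+01
6.538346e-03,7.477505e+01,7.208660e+01,1.818993e-01,2.506549e+00,7.208886e+01
6.539654e-03,7.473271e+01,7.204476e+01,1.818984e-01,2.506045e+00,7.204703e+01
6.682290e-03,7.030474e+01,6.767123e+01,1.818009e-01,2.451706e+00,6.767354e+01
7.111289e-03,5.896629e+01,5.648966e+01,1.815086e-01,2.295119e+00,5.649211e+01
7.112711e-03,4.541311e+02,4.516550e+02,1.815076e-01,2.294617e+00,3.180713e+02
7.360553e-03,4.113032e+02,4.089130e+02,1.813394e-01,2.208882e+00,2.920435e+02
8.107660e-03,3.110162e+02,3.088643e+02,1.808345e-01,1.971009e+00,2.287247e+02
8.332167e-03,2.874090e+02,2.853230e+02,1.806835e-01,1.905387e+00,2.132866e+02
8.333833e-03,2.872430e+02,2.851574e+02,1.806824e-01,1.904910e+00,2.131773e+02
8.930600e-03,2.352178e+02,2.332946e+02,1.802827e-01,1.742958e+00,1.783418e+02
9.837070e-03,1.779229e+02,1.762144e+02,1.796799e-01,1.528761e+00,1.385330e+02
1.083555e-02,1.346104e+02,1.331001e+02,1.790221e-01,1.331310e+00,1.072622e+02
1.193537e-02,1.018651e+02,1.005345e+02,1.783048e-01,1.152260e+00,8.281825e+01
1.314683e-02,7.710639e+01,7.593675e+01,1.775235e-01,9.921181e-01,6.378983e+01
1.448125e-02,5.838447e+01,5.735732e+01,1.766732e-01,8.504717e-01,4.902959e+01
1.595112e-02,4.422574e+01,4.332372e+01,1.757490e-01,7.262712e-01,3.761506e+01
1.757019e-02,3.351656e+01,3.272371e+01,1.747458e-01,6.181026e-01,2.881120e+01
1.935359e-02,2.541527e+01,2.471721e+01,1.736582e-01,5.244021e-01,2.203653e+01
1.999800e-02,2.314449e+01,2.247557e+01,1.732696e-01,4.956573e-01,2.011745e+01
2.000200e-02,2.313128e+01,2.246252e+01,1.732672e-01,4.954862e-01,2.010625e+01
2.131801e-02,1.928573e+01,1.866965e+01,1.724808e-01,4.435995e-01,1.683387e+01
2.348182e-02,1.464716e+01,1.410175e+01,1.712084e-01,3.742000e-01,1.284553e+01
2.586526e-02,1.113614e+01,1.065148e+01,1.698355e-01,3.148208e-01,9.792891e+00
2.849062e-02,8.477945e+00,8.045385e+00,1.683571e-01,2.642027e-01,7.459686e+00
3.138246e-02,6.464899e+00,6.076922e+00,1.667681e-01,2.212085e-01,5.678586e+00
3.456783e-02,4.939964e+00,4.590083e+00,1.650640e-01,1.848170e-01,4.320471e+00
3.807652e-02,3.784384e+00,3.467028e+00,1.632406e-01,1.541156e-01,3.285940e+00
4.194134e-02,2.908340e+00,2.618751e+00,1.612943e-01,1.282943e-01,2.498630e+00
4.619845e-02,2.243883e+00,1.978022e+00,1.592224e-01,1.066383e-01,1.899981e+00
5.088767e-02,1.739604e+00,1.494060e+00,1.570228e-01,8.852139e-02,1.445153e+00
5.605284e-02,1.356602e+00,1.128508e+00,1.546945e-01,7.339912e-02,1.099865e+00
6.174229e-02,1.065435e+00,8.523965e-01,1.522376e-01,6.080111e-02,8.379366e-01
6.800923e-02,8.438179e-01,6.438408e-01,1.496534e-01,5.032376e-02,6.393976e-01
7.491227e-02,6.748796e-01,4.863124e-01,1.469445e-01,4.162274e-02,4.890282e-01
7.610339e-02,6.513891e-01,4.645474e-01,1.464909e-01,4.035083e-02,4.682261e-01
7.611861e-02,6.510979e-01,4.642778e-01,1.464851e-01,4.033495e-02,4.679684e-01
8.251598e-02,5.458473e-01,3.673264e-01,1.441150e-01,3.440584e-02,3.752391e-01
9.089148e-02,4.470491e-01,2.774528e-01,1.411702e-01,2.842620e-02,2.892121e-01
1.001171e-01,3.711141e-01,2.095210e-01,1.381170e-01,2.347608e-02,2.241950e-01
1.102791e-01,3.096713e-01,1.553266e-01,1.349635e-01,1.938127e-02,1.723206e-01
1.214726e-01,2.628652e-01,1.151500e-01,1.317191e-01,1.599609e-02,1.339717e-01
1.338023e-01,2.269587e-01,8.536545e-02,1.283942e-01,1.319901e-02,1.056694e-01
1.473834e-01,1.991742e-01,6.328493e-02,1.250004e-01,1.088887e-02,8.482292e-02
1.623431e-01,1.774468e-01,4.691573e-02,1.215494e-01,8.981584e-03,6.950316e-02
1.788212e-01,1.602419e-01,3.478057e-02,1.180540e-01,7.407365e-03,5.827421e-02
1.969718e-01,1.464191e-01,2.578427e-02,1.145265e-01,6.108372e-03,5.006754e-02
2.169647e-01,1.351311e-01,1.911494e-02,1.109795e-01,5.036707e-03,4.408830e-02
2.389870e-01,1.257483e-01,1.417070e-02,1.074249e-01,4.152729e-03,3.974536e-02
2.632445e-01,1.178032e-01,1.050532e-02,1.038743e-01,3.423648e-03,3.659934e-02
2.899643e-01,1.109484e-01,7.788028e-03,1.003381e-01,2.822324e-03,3.432375e-02
3.193961e-01,1.052592e-01,6.107042e-03,9.682591e-02,2.326238e-03,3.300742e-02
3.518153e-01,1.002001e-01,4.937169e-03,9.334632e-02,1.916621e-03,3.212973e-02
3.875250e-01,9.547581e-02,3.991398e-03,8.990669e-02,1.577723e-03,3.140581e-02
4.268594e-01,9.103640e-02,3.226800e-03,8.651333e-02,1.296271e-03,3.079330e-02
4.701863e-01,8.684131e-02,2.608670e-03,8.317150e-02,1.061137e-03,3.025818e-02
5.179109e-01,8.285770e-02,2.108949e-03,7.988555e-02,8.632019e-04,2.977324e-02
5.704797e-01,7.905927e-02,1.704956e-03,7.665898e-02,6.953302e-04,2.931680e-02
6.283843e-01,7.542528e-02,1.378352e-03,7.349462e-02,5.523079e-04,2.887173e-02
6.921662e-01,7.193972e-02,1.114313e-03,7.039477e-02,4.306321e-04,2.842463e-02
7.624222e-01,6.859028e-02,9.008537e-04,6.736133e-02,3.281045e-04,2.796523e-02
8.398092e-01,6.536746e-02,7.282849e-04,6.439589e-02,2.432893e-04,2.748586e-02
9.250511e-01,6.226362e-02,5.887736e-04,6.149987e-02,1.749694e-04,2.698106e-02
1.018945e+00,5.927233e-02,4.759873e-04,5.867461e-02,1.217378e-04,2.644721e-02
1.122370e+00,5.638796e-02,3.848065e-04,5.592134e-02,8.181217e-05,2.588232e-02
1.236292e+00,5.360547e-02,3.110924e-04,5.324131e-02,5.307044e-05,2.528570e-02
1.361777e+00,5.092046e-02,2.514991e-04,5.063573e-02,3.323747e-05,2.465785e-02
1.500000e+00,4.832922e-02,2.033216e-04,4.810578e-02,2.011780e-05,2.400017e-02
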