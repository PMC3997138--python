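energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,1.206617e+02,1.176463e+02,1.813871e-01,2.833974e+00,1.176481e+02
5.507508e-03,9.166626e+01,8.886183e+01,1.810386e-01,2.623391e+00,8.886374e+01
5.988401e-03,7.230838e+01,6.969337e+01,1.807101e-01,2.434301e+00,6.969543e+01
5.989599e-03,5.598379e+02,5.572234e+02,1.807093e-01,2.433844e+00,4.239231e+02
6.066528e-03,5.395455e+02,5.369602e+02,1.806569e-01,2.404652e+00,4.101363e+02
6.538346e-03,4.344581e+02,4.320454e+02,1.803363e-01,2.232360e+00,3.373656e+02
6.539654e-03,4.342069e+02,4.317947e+02,1.803354e-01,2.231899e+00,3.371887e+02
6.682290e-03,4.079447e+02,4.055823e+02,1.802388e-01,2.182160e+00,3.186165e+02
7.111289e-03,3.407855e+02,3.385664e+02,1.799490e-01,2.039206e+00,2.703504e+02
7.112711e-03,3.405886e+02,3.383699e+02,1.799481e-01,2.038749e+00,2.702071e+02
7.360553e-03,3.084890e+02,3.063485e+02,1.797812e-01,1.960717e+00,2.467146e+02
8.107660e-03,2.333187e+02,2.313943e+02,1.792807e-01,1.745090e+00,1.905027e+02
8.332167e-03,2.156226e+02,2.137576e+02,1.791310e-01,1.685830e+00,1.770009e+02
8.333833e-03,2.154981e+02,2.136336e+02,1.791299e-01,1.685399e+00,1.769055e+02
8.930600e-03,1.764974e+02,1.747791e+02,1.787336e-01,1.539561e+00,1.467397e+02
9.837070e-03,1.335416e+02,1.320159e+02,1.781360e-01,1.347552e+00,1.127898e+02
1.083555e-02,1.010645e+02,9.971562e+01,1.774839e-01,1.171400e+00,8.653305e+01
1.193537e-02,7.650731e+01,7.531822e+01,1.767728e-01,1.012312e+00,6.628003e+01
1.314683e-02,5.793662e+01,5.689013e+01,1.759981e-01,8.704983e-01,5.069398e+01
1.448125e-02,4.389138e+01,4.297083e+01,1.751552e-01,7.453918e-01,3.872369e+01
1.595112e-02,3.326732e+01,3.245717e+01,1.742389e-01,6.359176e-01,2.954667e+01
1.757019e-02,2.522985e+01,2.451588e+01,1.732443e-01,5.407269e-01,2.252212e+01
1.935359e-02,1.914813e+01,1.851758e+01,1.721660e-01,4.583765e-01,1.715263e+01
1.999800e-02,1.744311e+01,1.683820e+01,1.717808e-01,4.331337e-01,1.563792e+01
2.000200e-02,1.743319e+01,1.682842e+01,1.717784e-01,4.329835e-01,1.562909e+01
2.131801e-02,1.454533e+01,1.398689e+01,1.709988e-01,3.874432e-01,1.305331e+01
2.348182e-02,1.106104e+01,1.056472e+01,1.697373e-01,3.265850e-01,9.927145e+00
2.586526e-02,8.422796e+00,7.979852e+00,1.683762e-01,2.745675e-01,7.545463e+00
2.849062e-02,6.424603e+00,6.027424e+00,1.669105e-01,2.302695e-01,5.732584e+00
3.138246e-02,4.910710e+00,4.552695e+00,1.653351e-01,1.926802e-01,4.353781e+00
3.456783e-02,3.763327e+00,3.438788e+00,1.636457e-01,1.608931e-01,3.305894e+00
3.807652e-02,2.893358e+00,2.597420e+00,1.618379e-01,1.340997e-01,2.510052e+00
4.194134e-02,2.233402e+00,1.961910e+00,1.599084e-01,1.115833e-01,1.906020e+00
4.619845e-02,1.732457e+00,1.481890e+00,1.578543e-01,9.271267e-02,1.447857e+00
5.088767e-02,1.351926e+00,1.119316e+00,1.556736e-01,7.693622e-02,1.100547e+00
5.605284e-02,1.062594e+00,8.454534e-01,1.533653e-01,6.377496e-02,8.374341e-01
6.174229e-02,8.423420e-01,6.385965e-01,1.509295e-01,5.281604e-02,6.382347e-01
6.800923e-02,6.744244e-01,4.823512e-01,1.483675e-01,4.370572e-02,4.875285e-01
7.491227e-02,5.461590e-01,3.643344e-01,1.456819e-01,3.614272e-02,3.735978e-01
7.610339e-02,5.282981e-01,3.480286e-01,1.452322e-01,3.503737e-02,3.578542e-01
7.611861e-02,5.280766e-01,3.478266e-01,1.452265e-01,3.502357e-02,3.576592e-01
8.251598e-02,4.479411e-01,2.751928e-01,1.428767e-01,2.987165e-02,2.875433e-01
9.089148e-02,3.724957e-01,2.078614e-01,1.399572e-01,2.467703e-02,2.226095e-01
1.001171e-01,3.142764e-01,1.569685e-01,1.369302e-01,2.037771e-02,1.736346e-01
1.102791e-01,2.669929e-01,1.163672e-01,1.338038e-01,1.682190e-02,1.346409e-01
1.214726e-01,2.307379e-01,8.626782e-02,1.305873e-01,1.388277e-02,1.058873e-01
1.338023e-01,2.026995e-01,6.395390e-02,1.272910e-01,1.145456e-02,8.472915e-02
1.473834e-01,1.807872e-01,4.741166e-02,1.239263e-01,9.449282e-03,6.919921e-02
1.623431e-01,1.634471e-01,3.514822e-02,1.205050e-01,7.793837e-03,5.783409e-02
1.788212e-01,1.495240e-01,2.605683e-02,1.170396e-01,6.427583e-03,4.954547e-02
1.969718e-01,1.381597e-01,1.931700e-02,1.135424e-01,5.300264e-03,4.352412e-02
2.169647e-01,1.287167e-01,1.432049e-02,1.100259e-01,4.370274e-03,3.916844e-02
2.389870e-01,1.207214e-01,1.061637e-02,1.065019e-01,3.603187e-03,3.603131e-02
2.632445e-01,1.138226e-01,7.870353e-03,1.029817e-01,2.970526e-03,3.378055e-02
2.899643e-01,1.077592e-01,5.834617e-03,9.947593e-02,2.448705e-03,3.216952e-02
3.193961e-01,1.025874e-01,4.575260e-03,9.599395e-02,2.018142e-03,3.126386e-02
3.518153e-01,9.790555e-02,3.698817e-03,9.254425e-02,1.662481e-03,3.067193e-02
3.875250e-01,9.349242e-02,2.990266e-03,8.913417e-02,1.367975e-03,3.017955e-02
4.268594e-01,8.931046e-02,2.417447e-03,8.576997e-02,1.123042e-03,2.975474e-02
4.701863e-01,8.532923e-02,1.954357e-03,8.245686e-02,9.180117e-04,2.937191e-02
5.179109e-01,8.152416e-02,1.579978e-03,7.919914e-02,7.450415e-04,2.901069e-02
5.704797e-01,7.787571e-02,1.277315e-03,7.600030e-02,5.980958e-04,2.865494e-02
6.283843e-01,7.436862e-02,1.032631e-03,7.286313e-02,4.728624e-04,2.829199e-02
6.921662e-01,7.099124e-02,8.348186e-04,6.978992e-02,3.665093e-04,2.791210e-02
7.624222e-01,6.773470e-02,6.748996e-04,6.678253e-02,2.772694e-04,2.750792e-02
8.398092e-01,6.459212e-02,5.456148e-04,6.384257e-02,2.039307e-04,2.707416e-02
9.250511e-01,6.155790e-02,4.410961e-04,6.097144e-02,1.453609e-04,2.660725e-02
1.018945e+00,5.862724e-02,3.565991e-04,5.817045e-02,1.001852e-04,2.610514e-02
1.122370e+00,5.579581e-02,2.882885e-04,5.544084e-02,6.667590e-05,2.556706e-02
1.236292e+00,5.305974e-02,2.330635e-04,5.278384e-02,4.283187e-05,2.499334e-02
1.361777e+00,5.041563e-02,1.884176e-04,5.020065e-02,2.657019e-05,2.438524e-02
1.500000e+00,4.786070e-02,1.523240e-04,4.769244e-02,1.593574e-05,2.374484e-02
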