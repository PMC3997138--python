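energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,9.094862e+02,9.039960e+02,1.720162e-01,5.318145e+00,9.039977e+02
5.507508e-03,6.879978e+02,6.828155e+02,1.716858e-01,5.010612e+00,6.828173e+02
5.988401e-03,5.404210e+02,5.355248e+02,1.713742e-01,4.724869e+00,5.355267e+02
5.989599e-03,5.401095e+02,5.352140e+02,1.713734e-01,4.724167e+00,5.352159e+02
6.066528e-03,5.206017e+02,5.157512e+02,1.713237e-01,4.679198e+00,5.157532e+02
6.538346e-03,4.195603e+02,4.149804e+02,1.710197e-01,4.408915e+00,4.149825e+02
6.539654e-03,4.193187e+02,4.147395e+02,1.710189e-01,4.408180e+00,4.147417e+02
6.682290e-03,3.940619e+02,3.895624e+02,1.709272e-01,4.328547e+00,3.895646e+02
7.111289e-03,3.294597e+02,3.251936e+02,1.706524e-01,4.095508e+00,3.251959e+02
7.112711e-03,3.292703e+02,3.250048e+02,1.706515e-01,4.094752e+00,3.250072e+02
7.360553e-03,2.983836e+02,2.942483e+02,1.704933e-01,3.964841e+00,2.942507e+02
8.107660e-03,2.260201e+02,2.222546e+02,1.700186e-01,3.595454e+00,2.222572e+02
8.332167e-03,2.089756e+02,2.053146e+02,1.698767e-01,3.491156e+00,2.053172e+02
8.333833e-03,2.088557e+02,2.051954e+02,1.698756e-01,3.490393e+00,2.051981e+02
8.930600e-03,1.712735e+02,1.678756e+02,1.694998e-01,3.228375e+00,1.678785e+02
9.837070e-03,1.298419e+02,1.268015e+02,1.689331e-01,2.871483e+00,1.268046e+02
1.083555e-02,9.847714e+01,9.577702e+01,1.683146e-01,2.531804e+00,9.578043e+01
1.193537e-02,7.472582e+01,7.234328e+01,1.676403e-01,2.214897e+00,7.234700e+01
1.314683e-02,5.673447e+01,5.464306e+01,1.669056e-01,1.924506e+00,5.464713e+01
1.448125e-02,4.310217e+01,4.127356e+01,1.661062e-01,1.662512e+00,4.127799e+01
1.595112e-02,3.276956e+01,3.117516e+01,1.652373e-01,1.429155e+00,3.117999e+01
1.757019e-02,2.493526e+01,2.354754e+01,1.642941e-01,1.223422e+00,2.355280e+01
1.935359e-02,1.899293e+01,1.778617e+01,1.632715e-01,1.043486e+00,1.779188e+01
1.999800e-02,1.732400e+01,1.617312e+01,1.629062e-01,9.879795e-01,1.617899e+01
2.000200e-02,1.142967e+02,1.131461e+02,1.629039e-01,9.876487e-01,3.785512e+01
2.131801e-02,9.509027e+01,9.404102e+01,1.621646e-01,8.870887e-01,3.532784e+01
2.348182e-02,7.194482e+01,7.103202e+01,1.609683e-01,7.518316e-01,3.077324e+01
2.586526e-02,5.444767e+01,5.365263e+01,1.596775e-01,6.353601e-01,2.604873e+01
2.849062e-02,4.121920e+01,4.052545e+01,1.582875e-01,5.354588e-01,2.159957e+01
3.138246e-02,3.121698e+01,3.061010e+01,1.567935e-01,4.500922e-01,1.763519e+01
3.456783e-02,2.365334e+01,2.312073e+01,1.551913e-01,3.774128e-01,1.422680e+01
3.807652e-02,1.793302e+01,1.746379e+01,1.534770e-01,3.157555e-01,1.136854e+01
4.194134e-02,1.360620e+01,1.319093e+01,1.516472e-01,2.636278e-01,9.015059e+00
4.619845e-02,1.033290e+01,9.963505e+00,1.496992e-01,2.196990e-01,7.104067e+00
5.088767e-02,7.856157e+00,7.525736e+00,1.476311e-01,1.827898e-01,5.569273e+00
5.605284e-02,5.981720e+00,5.684416e+00,1.454421e-01,1.518626e-01,4.347415e+00
6.174229e-02,4.562754e+00,4.293611e+00,1.431321e-01,1.260105e-01,3.381664e+00
6.800923e-02,3.488243e+00,3.243094e+00,1.407025e-01,1.044469e-01,2.622892e+00
7.491227e-02,2.674256e+00,2.449607e+00,1.381556e-01,8.649384e-02,2.029735e+00
7.610339e-02,2.561569e+00,2.339974e+00,1.377292e-01,8.386593e-02,1.946229e+00
7.611861e-02,2.560173e+00,2.338616e+00,1.377237e-01,8.383312e-02,1.945192e+00
8.251598e-02,2.057328e+00,1.850262e+00,1.354953e-01,7.157075e-02,1.568033e+00
9.089148e-02,1.589469e+00,1.397559e+00,1.327267e-01,5.918333e-02,1.209981e+00
1.001171e-01,1.234148e+00,1.055380e+00,1.298561e-01,4.891276e-02,9.329978e-01
1.102791e-01,9.496933e-01,7.823964e-01,1.268912e-01,4.040571e-02,7.067224e-01
1.214726e-01,7.372288e-01,5.800227e-01,1.238409e-01,3.336525e-02,5.360346e-01
1.338023e-01,5.782523e-01,4.299948e-01,1.207149e-01,2.754261e-02,4.075692e-01
1.473834e-01,4.590268e-01,3.187729e-01,1.175240e-01,2.272995e-02,3.110818e-01
1.623431e-01,3.693530e-01,2.363195e-01,1.142795e-01,1.875402e-02,2.387510e-01
1.788212e-01,3.016571e-01,1.751934e-01,1.109931e-01,1.547069e-02,1.846256e-01
1.969718e-01,2.503149e-01,1.298781e-01,1.076766e-01,1.276021e-02,1.441909e-01
2.169647e-01,2.111489e-01,9.628398e-02,1.043417e-01,1.052327e-02,1.140308e-01
2.389870e-01,1.810566e-01,7.137929e-02,1.009998e-01,8.677556e-03,9.156594e-02
2.632445e-01,1.577328e-01,5.291641e-02,9.766147e-02,7.154942e-03,7.485293e-02
2.899643e-01,1.394649e-01,3.922912e-02,9.433677e-02,5.899051e-03,6.243000e-02
3.193961e-01,1.266597e-01,3.076182e-02,9.103468e-02,4.863245e-03,5.480907e-02
3.518153e-01,1.166411e-01,2.486904e-02,8.776320e-02,4.008900e-03,4.952202e-02
3.875250e-01,1.079383e-01,2.010509e-02,8.452930e-02,3.303930e-03,4.520961e-02
4.268594e-01,1.003142e-01,1.625373e-02,8.133889e-02,2.721529e-03,4.167956e-02
4.701863e-01,9.357625e-02,1.314014e-02,7.819695e-02,2.239156e-03,3.877489e-02
5.179109e-01,8.756835e-02,1.062300e-02,7.510753e-02,1.837822e-03,3.636770e-02
5.704797e-01,8.216368e-02,8.588043e-03,7.207394e-02,1.501695e-03,3.435393e-02
6.283843e-01,7.725973e-02,6.942905e-03,6.909885e-02,1.217970e-03,3.264915e-02
6.921662e-01,7.277416e-02,5.612913e-03,6.618441e-02,9.768415e-04,3.118502e-02
7.624222e-01,6.864143e-02,4.537695e-03,6.333239e-02,7.713413e-04,2.990644e-02
8.398092e-01,6.480968e-02,3.668448e-03,6.054432e-02,5.969196e-04,2.876920e-02
9.250511e-01,6.123797e-02,2.965715e-03,5.782152e-02,4.507372e-04,2.773804e-02
1.018945e+00,5.789365e-02,2.397598e-03,5.516523e-02,3.308155e-04,2.678507e-02
1.122370e+00,5.475021e-02,1.938311e-03,5.257664e-02,2.352607e-04,2.588849e-02
1.236292e+00,5.178566e-02,1.567005e-03,5.005690e-02,1.617519e-04,2.503149e-02
1.361777e+00,4.898137e-02,1.266828e-03,4.760716e-02,1.073825e-04,2.420140e-02
1.500000e+00,4.632150e-02,1.024152e-03,4.522854e-02,6.881017e-05,2.338887e-02
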