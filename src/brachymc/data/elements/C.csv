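energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,2.565939e+01,2.497828e+01,1.963076e-01,4.848003e-01,2.497695e+01
5.507508e-03,1.873528e+01,1.811085e+01,1.959305e-01,4.285014e-01,1.811080e+01
5.988401e-03,1.425149e+01,1.367338e+01,1.955749e-01,3.825326e-01,1.367415e+01
5.989599e-03,1.424220e+01,1.366420e+01,1.955741e-01,3.824263e-01,1.366497e+01
6.066528e-03,1.366228e+01,1.309109e+01,1.955173e-01,3.756807e-01,1.309196e+01
6.538346e-03,1.071319e+01,1.018041e+01,1.951704e-01,3.376052e-01,1.018184e+01
6.539654e-03,1.070625e+01,1.017358e+01,1.951694e-01,3.375071e-01,1.017501e+01
6.682290e-03,9.984745e+00,9.462643e+00,1.950649e-01,3.270375e-01,9.464213e+00
7.111289e-03,8.171518e+00,7.678633e+00,1.947513e-01,2.981342e-01,7.680569e+00
7.112711e-03,8.166273e+00,7.673479e+00,1.947502e-01,2.980444e-01,7.675416e+00
7.360553e-03,7.317427e+00,6.839892e+00,1.945696e-01,2.829647e-01,6.842012e+00
8.107660e-03,5.381688e+00,4.944087e+00,1.940280e-01,2.435734e-01,4.946670e+00
8.332167e-03,4.937998e+00,4.510851e+00,1.938660e-01,2.332808e-01,4.513555e+00
8.333833e-03,4.934895e+00,4.507823e+00,1.938648e-01,2.332068e-01,4.510528e+00
8.930600e-03,3.975926e+00,3.573739e+00,1.934359e-01,2.087505e-01,3.576738e+00
9.837070e-03,2.954229e+00,2.583210e+00,1.927891e-01,1.782295e-01,2.586602e+00
1.083555e-02,2.210965e+00,1.867224e+00,1.920833e-01,1.516571e-01,1.871006e+00
1.193537e-02,1.669647e+00,1.349688e+00,1.913137e-01,1.286451e-01,1.353866e+00
1.314683e-02,1.274877e+00,9.755962e-01,1.904754e-01,1.088054e-01,9.801873e-01
1.448125e-02,9.865235e-01,7.051912e-01,1.895631e-01,9.176922e-02,7.102178e-01
1.595112e-02,7.755015e-01,5.097341e-01,1.885715e-01,7.719588e-02,5.152231e-01
1.757019e-02,6.207220e-01,3.684517e-01,1.874950e-01,6.477530e-02,3.744335e-01
1.935359e-02,5.068839e-01,2.663283e-01,1.863281e-01,5.422756e-02,2.728361e-01
1.999800e-02,4.755372e-01,2.385928e-01,1.859111e-01,5.103337e-02,2.452866e-01
2.000200e-02,4.753556e-01,2.384326e-01,1.859085e-01,5.101442e-02,2.451276e-01
2.131801e-02,4.228765e-01,1.925104e-01,1.850648e-01,4.530132e-02,1.995793e-01
2.348182e-02,3.606241e-01,1.391525e-01,1.836995e-01,3.777214e-02,1.468193e-01
2.586526e-02,3.142510e-01,1.005837e-01,1.822265e-01,3.144079e-02,1.088862e-01
2.849062e-02,2.794768e-01,7.270505e-02,1.806402e-01,2.613154e-02,8.168169e-02
3.138246e-02,2.531793e-01,5.255347e-02,1.789353e-01,2.169055e-02,6.224281e-02
3.456783e-02,2.330782e-01,3.798728e-02,1.771068e-01,1.798406e-02,4.842749e-02
3.807652e-02,2.175054e-01,2.745838e-02,1.751504e-01,1.489659e-02,3.868668e-02
4.194134e-02,2.052390e-01,1.984777e-02,1.730622e-01,1.232906e-02,3.189977e-02
4.619845e-02,1.953826e-01,1.434659e-02,1.708391e-01,1.019699e-02,2.725566e-02
5.088767e-02,1.872778e-01,1.037016e-02,1.684790e-01,8.428700e-03,2.416675e-02
5.605284e-02,1.804403e-01,7.495873e-03,1.659808e-01,6.963639e-03,2.220676e-02
6.174229e-02,1.745138e-01,5.418250e-03,1.633446e-01,5.750873e-03,2.106584e-02
6.800923e-02,1.692361e-01,3.916479e-03,1.605719e-01,4.747695e-03,2.051810e-02
7.491227e-02,1.644147e-01,2.830953e-03,1.576654e-01,3.918394e-03,2.039820e-02
7.610339e-02,1.636611e-01,2.684915e-03,1.571787e-01,3.797458e-03,2.041040e-02
7.611861e-02,1.636516e-01,2.683113e-03,1.571725e-01,3.795949e-03,2.041061e-02
8.251598e-02,1.599089e-01,2.046301e-03,1.546294e-01,3.233185e-03,2.058446e-02
9.089148e-02,1.556162e-01,1.479130e-03,1.514698e-01,2.667274e-03,2.098670e-02
1.001171e-01,1.514632e-01,1.069270e-03,1.481938e-01,2.200058e-03,2.153762e-02
1.102791e-01,1.474042e-01,7.794643e-04,1.448103e-01,1.814437e-03,2.219262e-02
1.214726e-01,1.433936e-01,5.682048e-04,1.413291e-01,1.496240e-03,2.290279e-02
1.338023e-01,1.394097e-01,4.142034e-04,1.377617e-01,1.233730e-03,2.363959e-02
1.473834e-01,1.354394e-01,3.019412e-04,1.341202e-01,1.017198e-03,2.438055e-02
1.623431e-01,1.314919e-01,2.357811e-04,1.304175e-01,8.386082e-04,2.512348e-02
1.788212e-01,1.275453e-01,1.869583e-04,1.266670e-01,6.913120e-04,2.583369e-02
1.969718e-01,1.236002e-01,1.482452e-04,1.228822e-01,5.697909e-04,2.649868e-02
2.169647e-01,1.196634e-01,1.175483e-04,1.190764e-01,4.694436e-04,2.711179e-02
2.389870e-01,1.157421e-01,9.320775e-05,1.152625e-01,3.864077e-04,2.766761e-02
2.632445e-01,1.118441e-01,7.390738e-05,1.114528e-01,3.174281e-04,2.816179e-02
2.899643e-01,1.079770e-01,5.860350e-05,1.076586e-01,2.597777e-04,2.859096e-02
3.193961e-01,1.041479e-01,4.646857e-05,1.038902e-01,2.112263e-04,2.895263e-02
3.518153e-01,1.003636e-01,3.684640e-05,1.001568e-01,1.700343e-04,2.924502e-02
3.875250e-01,9.663032e-02,2.921667e-05,9.646617e-02,1.349362e-04,2.946700e-02
4.268594e-01,9.295348e-02,2.316682e-05,9.282523e-02,1.050857e-04,2.961795e-02
4.701863e-01,8.933792e-02,1.836971e-05,8.923959e-02,7.995290e-05,2.969768e-02
5.179109e-01,8.578766e-02,1.456592e-05,8.571390e-02,5.918866e-05,2.970640e-02
5.704797e-01,8.230597e-02,1.154978e-05,8.225192e-02,4.249119e-05,2.964467e-02
6.283843e-01,7.889536e-02,9.158187e-06,7.885670e-02,2.950760e-05,2.951337e-02
6.921662e-01,7.555774e-02,7.261816e-06,7.553069e-02,1.979115e-05,2.931374e-02
7.624222e-01,7.229450e-02,5.758124e-06,7.227592e-02,1.281286e-05,2.904738e-02
8.398092e-01,6.910670e-02,4.565798e-06,6.909413e-02,8.008992e-06,2.871630e-02
9.250511e-01,6.599529e-02,3.620366e-06,6.598683e-02,4.838605e-06,2.832289e-02
1.018945e+00,6.296113e-02,2.870703e-06,6.295543e-02,2.830108e-06,2.786998e-02
1.122370e+00,6.000518e-02,2.276271e-06,6.000129e-02,1.606070e-06,2.736083e-02
1.236292e+00,5.712842e-02,1.804927e-06,5.712573e-02,8.865077e-07,2.679910e-02
1.361777e+00,5.433196e-02,1.431184e-06,5.433005e-02,4.772103e-07,2.618885e-02
1.500000e+00,5.161691e-02,1.134831e-06,5.161552e-02,2.511996e-07,2.553448e-02
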