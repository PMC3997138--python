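energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,4.904224e+02,4.883233e+02,1.770690e-01,1.921976e+00,4.561808e+02
5.507508e-03,3.633409e+02,3.614023e+02,1.767288e-01,1.761863e+00,3.398068e+02
5.988401e-03,2.823860e+02,2.805887e+02,1.764081e-01,1.620851e+00,2.651693e+02
5.989599e-03,2.822160e+02,2.804191e+02,1.764073e-01,1.620513e+00,2.650121e+02
6.066528e-03,2.715804e+02,2.698051e+02,1.763562e-01,1.598975e+00,2.551693e+02
6.538346e-03,2.167804e+02,2.151313e+02,1.760432e-01,1.473103e+00,2.043042e+02
6.539654e-03,2.166500e+02,2.150012e+02,1.760424e-01,1.472769e+00,2.041828e+02
6.682290e-03,2.030359e+02,2.014231e+02,1.759480e-01,1.436826e+00,1.915045e+02
7.111289e-03,1.683908e+02,1.668807e+02,1.756652e-01,1.334491e+00,1.591594e+02
7.112711e-03,1.682896e+02,1.667798e+02,1.756642e-01,1.334166e+00,1.590647e+02
7.360553e-03,1.518269e+02,1.503725e+02,1.755014e-01,1.278908e+00,1.436511e+02
8.107660e-03,1.135641e+02,1.122607e+02,1.750128e-01,1.128361e+00,1.077062e+02
8.332167e-03,1.046247e+02,1.033623e+02,1.748666e-01,1.087525e+00,9.928212e+01
8.333833e-03,1.045619e+02,1.032998e+02,1.748655e-01,1.087229e+00,9.922292e+01
8.930600e-03,8.497045e+01,8.380827e+01,1.744787e-01,9.876944e-01,8.072254e+01
9.837070e-03,6.359963e+01,6.256711e+01,1.738953e-01,8.586266e-01,6.047696e+01
1.083555e-02,4.762482e+01,4.670951e+01,1.732587e-01,7.420492e-01,4.529422e+01
1.193537e-02,3.568169e+01,3.487101e+01,1.725645e-01,6.381196e-01,3.391324e+01
1.314683e-02,2.675120e+01,2.603297e+01,1.718083e-01,5.464275e-01,2.538542e+01
1.448125e-02,2.007210e+01,1.943493e+01,1.709854e-01,4.661879e-01,1.899777e+01
1.595112e-02,1.507566e+01,1.450915e+01,1.700910e-01,3.964142e-01,1.421475e+01
1.757019e-02,1.133699e+01,1.083182e+01,1.691201e-01,3.360501e-01,1.063432e+01
1.935359e-02,8.538619e+00,8.086498e+00,1.680675e-01,2.840531e-01,7.954857e+00
1.999800e-02,7.759900e+00,7.324051e+00,1.676914e-01,2.681576e-01,7.209556e+00
2.000200e-02,7.755376e+00,7.319623e+00,1.676891e-01,2.680631e-01,7.205227e+00
2.131801e-02,6.443347e+00,6.036979e+00,1.669280e-01,2.394403e-01,5.950156e+00
2.348182e-02,4.873913e+00,4.506910e+00,1.656965e-01,2.013071e-01,4.450659e+00
2.586526e-02,3.697836e+00,3.364636e+00,1.643679e-01,1.688319e-01,3.329313e+00
2.849062e-02,2.816082e+00,2.511871e+00,1.629370e-01,1.412742e-01,2.490952e+00
3.138246e-02,2.154607e+00,1.875238e+00,1.613992e-01,1.179696e-01,1.864312e+00
3.456783e-02,1.658036e+00,1.399960e+00,1.597499e-01,9.832563e-02,1.396048e+00
3.807652e-02,1.284943e+00,1.045141e+00,1.579852e-01,8.181697e-02,1.046235e+00
4.194134e-02,1.004333e+00,7.802505e-01,1.561016e-01,6.798111e-02,7.849988e-01
4.619845e-02,7.930065e-01,5.824964e-01,1.540964e-01,5.641363e-02,5.899907e-01
5.088767e-02,6.335941e-01,4.348630e-01,1.519676e-01,4.676350e-02,4.444950e-01
5.605284e-02,5.130895e-01,3.246472e-01,1.497143e-01,3.872805e-02,3.360102e-01
6.174229e-02,4.217500e-01,2.423655e-01,1.473365e-01,3.204798e-02,2.551877e-01
6.800923e-02,3.522760e-01,1.809381e-01,1.448355e-01,2.650240e-02,1.950371e-01
7.491227e-02,2.991973e-01,1.350794e-01,1.422138e-01,2.190410e-02,1.503316e-01
7.610339e-02,2.917953e-01,1.287880e-01,1.417748e-01,2.123247e-02,1.442194e-01
7.611861e-02,2.917034e-01,1.287101e-01,1.417692e-01,2.122408e-02,1.441438e-01
8.251598e-02,2.584141e-01,1.008436e-01,1.394754e-01,1.809508e-02,1.171628e-01
9.089148e-02,2.268528e-01,7.528486e-02,1.366254e-01,1.494254e-02,9.260804e-02
1.001171e-01,2.021934e-01,5.618774e-02,1.336705e-01,1.233517e-02,7.446543e-02
1.102791e-01,1.817576e-01,4.095908e-02,1.306185e-01,1.017998e-02,6.015146e-02
1.214726e-01,1.657359e-01,2.985788e-02,1.274785e-01,8.399436e-03,4.992272e-02
1.338023e-01,1.529552e-01,2.176545e-02,1.242607e-01,6.929009e-03,4.266116e-02
1.473834e-01,1.425575e-01,1.586632e-02,1.209761e-01,5.715104e-03,3.754974e-02
1.623431e-01,1.347393e-01,1.238977e-02,1.176363e-01,4.713254e-03,3.481330e-02
1.788212e-01,1.279642e-01,9.824237e-03,1.142534e-01,3.886610e-03,3.293945e-02
1.969718e-01,1.218341e-01,7.789948e-03,1.108395e-01,3.204664e-03,3.154496e-02
2.169647e-01,1.162257e-01,6.176896e-03,1.074066e-01,2.642171e-03,3.051627e-02
2.389870e-01,1.110426e-01,4.897857e-03,1.039665e-01,2.178250e-03,2.976316e-02
2.632445e-01,1.062094e-01,3.883665e-03,1.005302e-01,1.795607e-03,2.921401e-02
2.899643e-01,1.016672e-01,3.079481e-03,9.710781e-02,1.479884e-03,2.881210e-02
3.193961e-01,9.736963e-02,2.441818e-03,9.370872e-02,1.219088e-03,2.851259e-02
3.518153e-01,9.328048e-02,1.936195e-03,9.034115e-02,1.003141e-03,2.828008e-02
3.875250e-01,8.937107e-02,1.535270e-03,8.701225e-02,8.235520e-04,2.808678e-02
4.268594e-01,8.561873e-02,1.217364e-03,8.372814e-02,6.732289e-04,2.791085e-02
4.701863e-01,8.200561e-02,9.652866e-04,8.049390e-02,5.464195e-04,2.773528e-02
5.179109e-01,7.851783e-02,7.654063e-04,7.731373e-02,4.386944e-04,2.754689e-02
5.704797e-01,7.514484e-02,6.069149e-04,7.419104e-02,3.468866e-04,2.733557e-02
6.283843e-01,7.187871e-02,4.812420e-04,7.112855e-02,2.689151e-04,2.709372e-02
6.921662e-01,6.871357e-02,3.815920e-04,6.812850e-02,2.034812e-04,2.681578e-02
7.624222e-01,6.564498e-02,3.025764e-04,6.519271e-02,1.496959e-04,2.649792e-02
8.398092e-01,6.266939e-02,2.399224e-04,6.232274e-02,1.067306e-04,2.613774e-02
9.250511e-01,5.978378e-02,1.902420e-04,5.951996e-02,7.358102e-05,2.573409e-02
1.018945e+00,5.698548e-02,1.508489e-04,5.678565e-02,4.898409e-05,2.528687e-02
1.122370e+00,5.427211e-02,1.196129e-04,5.412102e-02,3.147581e-05,2.479693e-02
1.236292e+00,5.164165e-02,9.484485e-05,5.152727e-02,1.953104e-05,2.426592e-02
1.361777e+00,4.909249e-02,7.520548e-05,4.900557e-02,1.171705e-05,2.369618e-02
1.500000e+00,4.662352e-02,5.963280e-05,4.655708e-02,6.808252e-06,2.309064e-02
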