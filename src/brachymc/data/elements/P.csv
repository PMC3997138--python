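energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,3.168263e+02,3.150043e+02,1.903088e-01,1.631708e+00,3.075958e+02
5.507508e-03,2.340151e+02,2.323388e+02,1.899433e-01,1.486382e+00,2.273788e+02
5.988401e-03,1.810998e+02,1.795502e+02,1.895986e-01,1.360006e+00,1.760257e+02
5.989599e-03,1.809890e+02,1.794397e+02,1.895977e-01,1.359705e+00,1.759181e+02
6.066528e-03,1.740558e+02,1.725257e+02,1.895427e-01,1.340536e+00,1.691828e+02
6.538346e-03,1.384133e+02,1.369949e+02,1.892064e-01,1.229205e+00,1.345328e+02
6.539654e-03,1.383287e+02,1.369105e+02,1.892055e-01,1.228911e+00,1.344504e+02
6.682290e-03,1.294973e+02,1.281108e+02,1.891041e-01,1.197339e+00,1.258582e+02
7.111289e-03,1.070722e+02,1.057754e+02,1.888001e-01,1.107972e+00,1.040284e+02
7.112711e-03,1.070068e+02,1.057103e+02,1.887991e-01,1.107690e+00,1.039648e+02
7.360553e-03,9.637849e+01,9.513011e+01,1.886240e-01,1.059754e+00,9.361256e+01
8.107660e-03,7.175826e+01,7.063990e+01,1.880989e-01,9.302611e-01,6.961798e+01
8.332167e-03,6.602554e+01,6.494219e+01,1.879418e-01,8.954088e-01,6.402838e+01
8.333833e-03,6.598531e+01,6.490221e+01,1.879407e-01,8.951566e-01,6.398915e+01
8.930600e-03,5.345263e+01,5.245443e+01,1.875249e-01,8.106728e-01,5.176673e+01
9.837070e-03,3.983957e+01,3.895061e+01,1.868979e-01,7.020579e-01,3.848833e+01
1.083555e-02,2.971420e+01,2.892320e+01,1.862137e-01,6.047869e-01,2.861301e+01
1.193537e-02,2.218137e+01,2.147724e+01,1.854676e-01,5.186611e-01,2.126970e+01
1.314683e-02,1.657590e+01,1.594816e+01,1.846548e-01,4.430823e-01,1.580997e+01
1.448125e-02,1.240347e+01,1.184248e+01,1.837704e-01,3.772182e-01,1.175119e+01
1.595112e-02,9.296707e+00,8.793763e+00,1.828091e-01,3.201347e-01,8.734260e+00
1.757019e-02,6.982558e+00,6.529905e+00,1.817656e-01,2.708871e-01,6.492003e+00
1.935359e-02,5.258059e+00,4.848852e+00,1.806343e-01,2.285724e-01,4.825701e+00
1.999800e-02,4.779594e+00,4.383706e+00,1.802301e-01,2.156579e-01,4.364419e+00
2.000200e-02,4.776816e+00,4.381007e+00,1.802276e-01,2.155811e-01,4.361742e+00
2.131801e-02,3.972331e+00,3.600568e+00,1.794096e-01,1.923534e-01,3.587561e+00
2.348182e-02,3.013194e+00,2.673641e+00,1.780861e-01,1.614666e-01,2.667685e+00
2.586526e-02,2.297222e+00,1.985342e+00,1.766580e-01,1.352221e-01,1.984364e+00
2.849062e-02,1.762357e+00,1.474237e+00,1.751202e-01,1.130002e-01,1.476855e+00
3.138246e-02,1.362425e+00,1.094711e+00,1.734674e-01,9.424672e-02,1.100002e+00
3.456783e-02,1.063054e+00,8.128895e-01,1.716948e-01,7.846930e-02,8.202454e-01
3.807652e-02,8.386514e-01,6.036200e-01,1.697982e-01,6.523328e-02,6.126410e-01
4.194134e-02,6.701560e-01,4.482246e-01,1.677737e-01,5.415763e-02,4.586516e-01
4.619845e-02,5.433634e-01,3.328341e-01,1.656186e-01,4.491070e-02,3.445015e-01
5.088767e-02,4.476860e-01,2.471496e-01,1.633306e-01,3.720583e-02,2.599535e-01
5.605284e-02,3.752293e-01,1.835236e-01,1.609088e-01,3.079690e-02,1.974000e-01
6.174229e-02,3.201044e-01,1.362775e-01,1.583532e-01,2.547380e-02,1.511874e-01
6.800923e-02,2.779176e-01,1.011943e-01,1.556652e-01,2.105813e-02,1.171137e-01
7.491227e-02,2.453895e-01,7.514296e-02,1.528475e-01,1.739910e-02,9.205542e-02
7.610339e-02,2.408210e-01,7.158049e-02,1.523756e-01,1.686485e-02,8.865371e-02
7.611861e-02,2.407642e-01,7.153642e-02,1.523696e-01,1.685818e-02,8.861169e-02
8.251598e-02,2.200723e-01,5.579822e-02,1.499043e-01,1.436980e-02,7.369037e-02
9.089148e-02,2.001385e-01,4.143358e-02,1.468412e-01,1.186374e-02,6.029144e-02
1.001171e-01,1.842173e-01,3.076008e-02,1.436653e-01,9.791859e-03,5.056683e-02
1.102791e-01,1.708881e-01,2.242312e-02,1.403852e-01,8.079840e-03,4.315802e-02
1.214726e-01,1.600220e-01,1.634575e-02,1.370104e-01,6.665802e-03,3.798201e-02
1.338023e-01,1.509659e-01,1.191553e-02,1.335520e-01,5.498310e-03,3.442073e-02
1.473834e-01,1.432425e-01,8.686048e-03,1.300218e-01,4.534669e-03,3.202193e-02
1.623431e-01,1.369545e-01,6.782799e-03,1.264323e-01,3.739487e-03,3.090507e-02
1.788212e-01,1.312581e-01,5.378296e-03,1.227964e-01,3.083451e-03,3.023778e-02
1.969718e-01,1.259341e-01,4.264621e-03,1.191272e-01,2.542303e-03,2.980729e-02
2.169647e-01,1.209152e-01,3.381553e-03,1.154377e-01,2.095975e-03,2.954908e-02
2.389870e-01,1.161495e-01,2.681340e-03,1.117403e-01,1.727860e-03,2.941181e-02
2.632445e-01,1.115973e-01,2.126120e-03,1.080470e-01,1.424184e-03,2.935475e-02
2.899643e-01,1.072281e-01,1.685868e-03,1.043688e-01,1.173472e-03,2.934565e-02
3.193961e-01,1.030184e-01,1.336778e-03,1.007155e-01,9.661029e-04,2.935913e-02
3.518153e-01,9.895011e-02,1.059973e-03,9.709617e-02,7.939686e-04,2.937525e-02
3.875250e-01,9.500912e-02,8.404864e-04,9.351837e-02,6.502636e-04,2.937846e-02
4.268594e-01,9.118453e-02,6.664482e-04,8.998869e-02,5.293928e-04,2.935669e-02
4.701863e-01,8.746802e-02,5.284479e-04,8.651262e-02,4.269513e-04,2.930069e-02
5.179109e-01,8.385338e-02,4.190230e-04,8.309467e-02,3.396947e-04,2.920345e-02
5.704797e-01,8.033616e-02,3.322566e-04,7.973848e-02,2.654242e-04,2.905978e-02
6.283843e-01,7.691322e-02,2.634568e-04,7.644700e-02,2.027539e-04,2.886603e-02
6.921662e-01,7.358232e-02,2.089032e-04,7.322263e-02,1.507906e-04,2.861980e-02
7.624222e-01,7.034177e-02,1.656460e-04,7.006733e-02,1.088038e-04,2.831980e-02
8.398092e-01,6.719007e-02,1.313459e-04,6.698276e-02,7.596857e-05,2.796569e-02
9.250511e-01,6.412580e-02,1.041483e-04,6.397041e-02,5.123955e-05,2.755803e-02
1.018945e+00,6.114759e-02,8.258252e-05,6.103165e-02,3.336033e-05,2.709812e-02
1.122370e+00,5.825423e-02,6.548229e-05,5.816778e-02,2.096858e-05,2.658801e-02
1.236292e+00,5.544475e-02,5.192298e-05,5.538009e-02,1.273579e-05,2.603035e-02
1.361777e+00,5.271849e-02,4.117137e-05,5.266984e-02,7.486713e-06,2.542836e-02
1.500000e+00,5.007517e-02,3.264609e-05,5.003826e-02,4.268493e-06,2.478574e-02
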