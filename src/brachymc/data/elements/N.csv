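energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,3.927482e+01,3.847640e+01,1.963893e-01,6.020304e-01,3.846648e+01
5.507508e-03,2.870887e+01,2.797825e+01,1.960121e-01,5.346124e-01,2.797252e+01
5.988401e-03,2.188079e+01,2.120612e+01,1.956564e-01,4.790108e-01,2.120293e+01
5.989599e-03,2.186662e+01,2.119209e+01,1.956555e-01,4.788816e-01,2.118890e+01
6.066528e-03,2.098165e+01,2.031537e+01,1.955988e-01,4.706808e-01,2.031250e+01
6.538346e-03,1.647345e+01,1.585400e+01,1.952517e-01,4.241953e-01,1.585271e+01
6.539654e-03,1.646283e+01,1.584351e+01,1.952507e-01,4.240751e-01,1.584222e+01
6.682290e-03,1.535764e+01,1.475126e+01,1.951461e-01,4.112355e-01,1.475036e+01
7.111289e-03,1.257563e+01,1.200513e+01,1.948324e-01,3.756647e-01,1.200518e+01
7.112711e-03,1.256757e+01,1.199719e+01,1.948313e-01,3.755539e-01,1.199723e+01
7.360553e-03,1.126266e+01,1.071109e+01,1.946507e-01,3.569247e-01,1.071157e+01
8.107660e-03,8.279617e+00,7.777461e+00,1.941088e-01,3.080465e-01,7.778966e+00
8.332167e-03,7.594208e+00,7.105035e+00,1.939467e-01,2.952266e-01,7.106780e+00
8.333833e-03,7.589412e+00,7.100332e+00,1.939455e-01,2.951344e-01,7.102079e+00
8.930600e-03,6.105432e+00,5.647317e+00,1.935164e-01,2.645981e-01,5.649605e+00
9.837070e-03,4.519815e+00,4.100592e+00,1.928694e-01,2.263534e-01,4.103515e+00
1.083555e-02,3.362602e+00,2.977494e+00,1.921633e-01,1.929448e-01,2.980966e+00
1.193537e-02,2.517326e+00,2.161998e+00,1.913934e-01,1.639347e-01,2.165972e+00
1.314683e-02,1.899276e+00,1.569855e+00,1.905547e-01,1.388661e-01,1.574313e+00
1.448125e-02,1.446829e+00,1.139893e+00,1.896420e-01,1.172948e-01,1.144832e+00
1.595112e-02,1.115146e+00,8.276911e-01,1.886500e-01,9.880503e-02,8.331233e-01
1.757019e-02,8.715863e-01,6.009974e-01,1.875731e-01,8.301572e-02,6.069428e-01
1.935359e-02,6.923795e-01,4.363922e-01,1.864057e-01,6.958167e-02,4.428769e-01
1.999800e-02,6.430435e-01,3.915466e-01,1.859885e-01,6.550829e-02,3.982209e-01
2.000200e-02,6.427576e-01,3.912875e-01,1.859860e-01,6.548412e-02,3.979629e-01
2.131801e-02,5.602041e-01,3.168701e-01,1.851419e-01,5.819204e-02,3.239250e-01
2.348182e-02,4.624281e-01,2.300836e-01,1.837760e-01,4.856844e-02,2.377424e-01
2.586526e-02,3.898321e-01,1.670667e-01,1.823024e-01,4.046294e-02,1.753653e-01
2.849062e-02,3.356809e-01,1.213094e-01,1.807154e-01,3.365610e-02,1.302849e-01
3.138246e-02,2.950492e-01,8.808434e-02,1.790098e-01,2.795504e-02,9.777448e-02
3.456783e-02,2.643312e-01,6.395920e-02,1.771806e-01,2.319144e-02,7.440163e-02
3.807652e-02,2.408844e-01,4.644162e-02,1.752233e-01,1.921944e-02,5.767318e-02
4.194134e-02,2.227696e-01,3.372188e-02,1.731342e-01,1.591350e-02,4.577796e-02
4.619845e-02,2.085623e-01,2.448590e-02,1.709102e-01,1.316623e-02,3.739974e-02
5.088767e-02,1.972150e-01,1.777954e-02,1.685491e-01,1.088628e-02,3.158147e-02
5.605284e-02,1.879562e-01,1.290996e-02,1.660499e-01,8.996289e-03,2.762671e-02
6.174229e-02,1.802178e-01,9.374090e-03,1.634127e-01,7.431075e-03,2.502802e-02
6.800923e-02,1.735813e-01,6.806650e-03,1.606388e-01,6.135871e-03,2.341507e-02
7.491227e-02,1.677383e-01,4.942399e-03,1.577310e-01,5.064825e-03,2.251688e-02
7.610339e-02,1.668437e-01,4.690907e-03,1.572441e-01,4.908610e-03,2.242371e-02
7.611861e-02,1.668324e-01,4.687802e-03,1.572380e-01,4.906660e-03,2.242261e-02
8.251598e-02,1.624622e-01,3.588741e-03,1.546938e-01,4.179643e-03,2.213457e-02
9.089148e-02,1.575871e-01,2.605832e-03,1.515329e-01,3.448416e-03,2.212150e-02
1.001171e-01,1.529924e-01,1.892219e-03,1.482555e-01,2.844605e-03,2.236908e-02
1.102791e-01,1.485961e-01,1.379368e-03,1.448706e-01,2.346170e-03,2.280142e-02
1.214726e-01,1.443283e-01,1.005516e-03,1.413880e-01,1.934833e-03,2.334939e-02
1.338023e-01,1.401475e-01,7.329892e-04,1.378191e-01,1.595449e-03,2.396805e-02
1.473834e-01,1.360259e-01,5.343260e-04,1.341761e-01,1.315484e-03,2.462295e-02
1.623431e-01,1.319737e-01,4.172468e-04,1.304719e-01,1.084566e-03,2.531531e-02
1.788212e-01,1.279448e-01,3.308482e-04,1.267198e-01,8.941155e-04,2.598826e-02
1.969718e-01,1.239327e-01,2.623400e-04,1.229334e-01,7.370233e-04,2.662374e-02
2.169647e-01,1.199414e-01,2.080177e-04,1.191260e-01,6.073792e-04,2.721350e-02
2.389870e-01,1.159757e-01,1.649438e-04,1.153105e-01,5.002396e-04,2.775083e-02
2.632445e-01,1.120415e-01,1.307892e-04,1.114992e-01,4.114440e-04,2.823037e-02
2.899643e-01,1.081446e-01,1.037069e-04,1.077034e-01,3.374897e-04,2.864795e-02
3.193961e-01,1.042912e-01,8.223245e-05,1.039335e-01,2.754673e-04,2.900043e-02
3.518153e-01,1.004867e-01,6.520471e-05,1.001985e-01,2.230427e-04,2.928554e-02
3.875250e-01,9.673649e-02,5.170288e-05,9.650634e-02,1.784494e-04,2.950175e-02
4.268594e-01,9.304534e-02,4.099685e-05,9.286389e-02,1.404510e-04,2.964810e-02
4.701863e-01,8.941752e-02,3.250770e-05,8.927676e-02,1.082508e-04,2.972418e-02
5.179109e-01,8.585672e-02,2.577638e-05,8.574960e-02,8.134974e-05,2.972998e-02
5.704797e-01,8.236600e-02,2.043891e-05,8.228618e-02,5.938391e-05,2.966590e-02
6.283843e-01,7.894773e-02,1.620666e-05,7.888954e-02,4.198374e-05,2.953270e-02
6.921662e-01,7.560368e-02,1.285077e-05,7.556214e-02,2.868807e-05,2.933153e-02
7.624222e-01,7.233514e-02,1.018978e-05,7.230602e-02,1.892563e-05,2.906391e-02
8.398092e-01,6.914304e-02,8.079801e-06,6.912290e-02,1.205168e-05,2.873177e-02
9.250511e-01,6.602813e-02,6.406730e-06,6.601431e-02,7.412690e-06,2.833747e-02
1.018945e+00,6.299114e-02,5.080099e-06,6.298165e-02,4.409875e-06,2.788380e-02
1.122370e+00,6.003285e-02,4.028171e-06,6.002628e-02,2.542348e-06,2.737397e-02
1.236292e+00,5.715414e-02,3.194064e-06,5.714952e-02,1.423686e-06,2.681165e-02
1.361777e+00,5.435598e-02,2.532675e-06,5.435267e-02,7.763974e-07,2.620086e-02
1.500000e+00,5.163944e-02,2.008238e-06,5.163702e-02,4.134406e-07,2.554599e-02
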