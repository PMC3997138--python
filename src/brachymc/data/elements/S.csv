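energy_MeV,mu_rho_total,mu_rho_pe,mu_rho_incoh,mu_rho_coh,mu_en_rho
5.000000e-03,3.909441e+02,3.889192e+02,1.961198e-01,1.828757e+00,3.758729e+02
5.507508e-03,2.890676e+02,2.872023e+02,1.957431e-01,1.669607e+00,2.784566e+02
5.988401e-03,2.240393e+02,2.223133e+02,1.953879e-01,1.530583e+00,2.160880e+02
5.989599e-03,2.239030e+02,2.221773e+02,1.953870e-01,1.530251e+00,2.159571e+02
6.066528e-03,2.153745e+02,2.136701e+02,1.953303e-01,1.509112e+00,2.077640e+02
6.538346e-03,1.714963e+02,1.699153e+02,1.949837e-01,1.386066e+00,1.655583e+02
6.539654e-03,1.713921e+02,1.698114e+02,1.949827e-01,1.385741e+00,1.654579e+02
6.682290e-03,1.605099e+02,1.589643e+02,1.948783e-01,1.350762e+00,1.549762e+02
7.111289e-03,1.328562e+02,1.314101e+02,1.945650e-01,1.251548e+00,1.283129e+02
7.112711e-03,1.327755e+02,1.313297e+02,1.945639e-01,1.251233e+00,1.282350e+02
7.360553e-03,1.196571e+02,1.182648e+02,1.943835e-01,1.197891e+00,1.155722e+02
8.107660e-03,8.923275e+01,8.798554e+01,1.938424e-01,1.053368e+00,8.616806e+01
8.332167e-03,8.214015e+01,8.093211e+01,1.936805e-01,1.014366e+00,7.930577e+01
8.333833e-03,8.209037e+01,8.088260e+01,1.936793e-01,1.014083e+00,7.925759e+01
8.930600e-03,6.657127e+01,6.545866e+01,1.932508e-01,9.193593e-01,6.423236e+01
9.837070e-03,4.968916e+01,4.869933e+01,1.926047e-01,7.972210e-01,4.787243e+01
1.083555e-02,3.711030e+01,3.623088e+01,1.918996e-01,6.875219e-01,3.567386e+01
1.193537e-02,2.773601e+01,2.695471e+01,1.911307e-01,5.901674e-01,2.658011e+01
1.314683e-02,2.074839e+01,2.005352e+01,1.902932e-01,5.045812e-01,1.980227e+01
1.448125e-02,1.553850e+01,1.491923e+01,1.893817e-01,4.298914e-01,1.475146e+01
1.595112e-02,1.165295e+01,1.109947e+01,1.883911e-01,3.650858e-01,1.098825e+01
1.757019e-02,8.754118e+00,8.257680e+00,1.873157e-01,3.091224e-01,8.184830e+00
1.935359e-02,6.590617e+00,6.143472e+00,1.861498e-01,2.609951e-01,6.096733e+00
1.999800e-02,5.989736e+00,5.557704e+00,1.857333e-01,2.462981e-01,5.517780e+00
2.000200e-02,5.986246e+00,5.554305e+00,1.857307e-01,2.462107e-01,5.514419e+00
2.131801e-02,4.975218e+00,4.570564e+00,1.848878e-01,2.197662e-01,4.541666e+00
2.348182e-02,3.768468e+00,3.400366e+00,1.835238e-01,1.845783e-01,3.383737e+00
2.586526e-02,2.866480e+00,2.529772e+00,1.820522e-01,1.546555e-01,2.521663e+00
2.849062e-02,2.191844e+00,1.882077e+00,1.804674e-01,1.292996e-01,1.879965e+00
3.138246e-02,1.686860e+00,1.400210e+00,1.787641e-01,1.078857e-01,1.402406e+00
3.456783e-02,1.308511e+00,1.041715e+00,1.769374e-01,8.985813e-02,1.047091e+00
3.807652e-02,1.024714e+00,7.750056e-01,1.749828e-01,7.472520e-02,7.828092e-01
4.194134e-02,8.115335e-01,5.765815e-01,1.728966e-01,6.205536e-02,5.863161e-01
4.619845e-02,6.511078e-01,4.289597e-01,1.706757e-01,5.147239e-02,4.402991e-01
5.088767e-02,5.301019e-01,3.191335e-01,1.683178e-01,4.265061e-02,3.318650e-01
5.605284e-02,4.385580e-01,2.374260e-01,1.658220e-01,3.530998e-02,2.514123e-01
6.174229e-02,3.690375e-01,1.766380e-01,1.631884e-01,2.921114e-02,1.917907e-01
6.800923e-02,3.159824e-01,1.314135e-01,1.604183e-01,2.415064e-02,1.476751e-01
7.491227e-02,2.752387e-01,9.776778e-02,1.575146e-01,1.995636e-02,1.150993e-01
7.610339e-02,2.695337e-01,9.316152e-02,1.570283e-01,1.934387e-02,1.106647e-01
7.611861e-02,2.694629e-01,9.310454e-02,1.570222e-01,1.933623e-02,1.106099e-01
8.251598e-02,2.437011e-01,7.273637e-02,1.544815e-01,1.648326e-02,9.110894e-02
9.089148e-02,2.190483e-01,5.411373e-02,1.513249e-01,1.360961e-02,7.350278e-02
1.001171e-01,1.995347e-01,4.024910e-02,1.480521e-01,1.123351e-02,6.063045e-02
1.102791e-01,1.832820e-01,2.934032e-02,1.446717e-01,9.269899e-03,5.068837e-02
1.214726e-01,1.702300e-01,2.138817e-02,1.411940e-01,7.647911e-03,4.367186e-02
1.338023e-01,1.595299e-01,1.559130e-02,1.376300e-01,6.308624e-03,3.877493e-02
1.473834e-01,1.505606e-01,1.136556e-02,1.339919e-01,5.203116e-03,3.540820e-02
1.623431e-01,1.434588e-01,8.875192e-03,1.302928e-01,4.290820e-03,3.372992e-02
1.788212e-01,1.371214e-01,7.037420e-03,1.265459e-01,3.538131e-03,3.265302e-02
1.969718e-01,1.312621e-01,5.580193e-03,1.227647e-01,2.917235e-03,3.190067e-02
2.169647e-01,1.257923e-01,4.424712e-03,1.189625e-01,2.405123e-03,3.138972e-02
2.389870e-01,1.206435e-01,3.508494e-03,1.151523e-01,1.982755e-03,3.105406e-02
2.632445e-01,1.157625e-01,2.781996e-03,1.113462e-01,1.634352e-03,3.084124e-02
2.899643e-01,1.111083e-01,2.205932e-03,1.075556e-01,1.346785e-03,3.070972e-02
3.193961e-01,1.066491e-01,1.749154e-03,1.037908e-01,1.109060e-03,3.062674e-02
3.518153e-01,1.023598e-01,1.386959e-03,1.000609e-01,9.119197e-04,3.056653e-02
3.875250e-01,9.822124e-02,1.099764e-03,9.637389e-02,7.475781e-04,3.050891e-02
4.268594e-01,9.421807e-02,8.720376e-04,9.273644e-02,6.095918e-04,3.043817e-02
4.701863e-01,9.033853e-02,6.914662e-04,8.915423e-02,4.928286e-04,3.034214e-02
5.179109e-01,8.657364e-02,5.482854e-04,8.563191e-02,3.934450e-04,3.021155e-02
5.704797e-01,8.291679e-02,4.347528e-04,8.217325e-02,3.087859e-04,3.003940e-02
6.283843e-01,7.936316e-02,3.447293e-04,7.878127e-02,2.371569e-04,2.982063e-02
6.921662e-01,7.590928e-02,2.733468e-04,7.545844e-02,1.774884e-04,2.955172e-02
7.624222e-01,7.255250e-02,2.167453e-04,7.220679e-02,1.289661e-04,2.923054e-02
8.398092e-01,6.929063e-02,1.718642e-04,6.902804e-02,9.072388e-05,2.885610e-02
9.250511e-01,6.612166e-02,1.362766e-04,6.592371e-02,6.167053e-05,2.842843e-02
1.018945e+00,6.304374e-02,1.080580e-04,6.289521e-02,4.046930e-05,2.794849e-02
1.122370e+00,6.005522e-02,8.568260e-05,5.994390e-02,2.563553e-05,2.741805e-02
1.236292e+00,5.715472e-02,6.794045e-05,5.707109e-02,1.568773e-05,2.683960e-02
1.361777e+00,5.434124e-02,5.387213e-05,5.427808e-02,9.287770e-06,2.621624e-02
1.500000e+00,5.161420e-02,4.271692e-05,5.156615e-02,5.330439e-06,2.555163e-02
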