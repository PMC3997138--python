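material,energy_MeV,mu_rho,mu_en_rho
water,0.03,0.3756,0.1557
water,0.05,0.2269,0.04223
water,0.08,0.1837,
water,0.1,0.1707,0.02546
water,0.2,0.137,0.02967
water,0.3,0.1186,0.03192
water,0.5,0.09687,0.03299
water,1.0,0.07072,0.03103
dry_air,0.1,0.1541,0.02325
dry_air,0.3,0.1067,0.02872
dry_air,0.5,0.08712,0.02966
dry_air,1.0,0.06358,0.02789
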