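tissue,eps_inf,eps_static,sigma,tau,cole_cole
water,4.65,77.5,0.0,8.8e-12,
blood,,,,,"{""eps_inf"": 4.0, ""delta_eps"": [56.0, 5200.0], ""tau"": [8.377e-12, 1.3263e-7], ""alpha"": [0.10, 0.10], ""sigma"": 0.70}"
grey_matter,,,,,"{""eps_inf"": 4.0, ""delta_eps"": [45.0, 400.0], ""tau"": [7.958e-12, 1.5915e-8], ""alpha"": [0.10, 0.15], ""sigma"": 0.02}"
white_matter,,,,,"{""eps_inf"": 4.0, ""delta_eps"": [32.0, 100.0], ""tau"": [7.958e-12, 7.958e-9], ""alpha"": [0.10, 0.10], ""sigma"": 0.02}"
csf,,,,,"{""eps_inf"": 4.0, ""delta_eps"": [65.0, 40.0], ""tau"": [7.958e-12, 1.592e-9], ""alpha"": [0.10, 0.0], ""sigma"": 2.0}"
fat,,,,,"{""eps_inf"": 2.5, ""delta_eps"": [9.0, 35.0], ""tau"": [7.958e-12, 1.5915e-8], ""alpha"": [0.20, 0.10], ""sigma"": 0.035}"
muscle,,,,,"{""eps_inf"": 4.0, ""delta_eps"": [50.0, 7000.0], ""tau"": [7.234e-12, 3.5368e-7], ""alpha"": [0.10, 0.10], ""sigma"": 0.20}"
skin,,,,,"{""eps_inf"": 4.0, ""delta_eps"": [32.0, 1100.0], ""tau"": [7.234e-12, 3.2481e-8], ""alpha"": [0.0, 0.20], ""sigma"": 0.0002}"
skull,,,,,"{""eps_inf"": 2.5, ""delta_eps"": [10.0, 180.0], ""tau"": [1.3263e-11, 7.958e-8], ""alpha"": [0.20, 0.20], ""sigma"": 0.02}"
nail,,,,,"{""eps_inf"": 2.5, ""delta_eps"": [10.0, 180.0], ""tau"": [1.3263e-11, 7.958e-8], ""alpha"": [0.20, 0.20], ""sigma"": 0.02}"
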