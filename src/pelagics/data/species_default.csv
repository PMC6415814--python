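species_id,L_inf,k_vb,a0,q,b_lw,a_R,b_R,d_r,phi,Q10,gamma,delta,beta,CAL_f,spawn_peak,spawn_sd,longevity
anchovy,18,1.05,-0.3,0.0045,3.1,0.07,0.8,2.0,1.5,2.0,0.15,0.16,0.08,5500,135,15,4
sardine,24,0.5,-0.45,0.0075,3.05,0.075,0.8,2.0,1.5,2.0,0.15,0.16,0.08,6000,60,15,8
herring,34,0.33,-0.5,0.0055,3.1,0.065,0.8,2.0,1.3,2.0,0.15,0.16,0.08,6500,75,15,12
rudderfish,30,0.45,-0.4,0.015,3.0,0.06,0.8,2.0,1.2,2.0,0.15,0.16,0.08,5000,150,15,8
saury,33,1.1,-0.3,0.0025,3.15,0.07,0.8,2.0,1.4,2.0,0.15,0.16,0.08,7000,320,15,2
chub_mackerel,42,0.38,-0.55,0.0065,3.1,0.06,0.8,2.0,1.0,2.1,0.15,0.16,0.08,6000,105,15,10
spotted_mackerel,44,0.35,-0.5,0.0065,3.1,0.06,0.8,2.0,1.0,2.1,0.15,0.16,0.08,6000,120,15,10
jack_mackerel,38,0.4,-0.4,0.009,3.05,0.06,0.8,2.0,1.1,2.1,0.15,0.16,0.08,5500,105,15,10
mackerel_scad,40,0.42,-0.4,0.008,3.0,0.06,0.8,2.0,1.1,2.1,0.15,0.16,0.08,5500,180,15,8
spanish_mackerel,100,0.3,-0.35,0.005,3.05,0.08,0.79,1.2,0.8,2.2,0.15,0.16,0.08,5500,135,15,10
skipjack,90,0.35,-0.45,0.016,3.0,0.12,0.79,1.5,0.9,2.2,0.15,0.16,0.08,6000,180,15,10
albacore,110,0.2,-0.6,0.018,3.0,0.11,0.79,1.2,0.8,2.2,0.15,0.16,0.08,6500,100,15,12
yellowfin,160,0.25,-0.4,0.017,3.0,0.12,0.79,1.0,0.7,2.2,0.15,0.16,0.08,6500,170,15,9
bluefin,250,0.14,-0.55,0.018,3.0,0.16,0.79,0.8,0.55,2.2,0.15,0.16,0.08,6500,150,15,11
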