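group,label,theta_per_1000,sigma,lcb,ucb
all,All,9.40,0.41,8.60,10.20
site,Viwandani,8.32,0.49,7.36,9.27
site,Korogocho,11.15,0.72,9.75,12.56
village_viwandani,Paradise A,10.62,2.64,5.44,15.80
village_viwandani,Paradise B,23.05,3.56,16.07,30.02
village_viwandani,Paradise C,5.32,2.01,1.39,9.26
village_viwandani,Sinai Original,7.73,1.77,4.27,11.19
village_viwandani,Sinai Reli,6.61,1.76,3.16,10.07
village_viwandani,Jamaica,5.66,1.13,3.44,7.87
village_viwandani,Lunga Lunga Center,10.99,1.73,7.60,14.38
village_viwandani,Milimani,18.05,2.31,13.52,22.58
village_viwandani,Donholm,2.64,0.88,0.92,4.37
village_viwandani,Riverside,4.29,1.07,2.19,6.38
village_viwandani,Kingstone,3.91,0.89,2.15,5.66
village_viwandani,Uchumi,10.52,2.18,6.24,14.80
village_korogocho,Korogocho B,16.96,2.73,11.62,22.31
village_korogocho,Korogocho A,9.28,1.63,6.08,12.48
village_korogocho,Grogon A,9.97,2.34,5.38,14.55
village_korogocho,Grogon B,9.76,2.80,4.26,15.25
village_korogocho,Gitathuru,10.54,1.80,7.01,14.06
village_korogocho,Highridge,13.81,1.55,10.76,16.85
village_korogocho,Nyayo,4.20,2.10,0.09,8.31
village_korogocho,Kisumu Ndogo,8.01,1.66,4.75,11.26
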