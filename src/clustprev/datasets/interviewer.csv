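site,label,sex,theta_per_1000,sigma,lcb,ucb
Viwandani,Interviewer 1,F,8.92,2.46,4.09,13.74
Viwandani,Interviewer 3,F,9.72,2.28,5.25,14.20
Viwandani,Interviewer 8,F,1.11,0.79,-0.43,2.66
Viwandani,Interviewer 10,F,2.07,1.03,0.04,4.10
Viwandani,Interviewer 11,F,4.62,1.46,1.76,7.47
Viwandani,Interviewer 13,F,3.66,1.38,0.95,6.37
Viwandani,Interviewer 14,F,1.93,0.86,0.24,3.62
Viwandani,Interviewer 16,F,20.06,2.78,14.61,25.50
Viwandani,Interviewer 17,F,10.86,2.25,6.44,15.27
Viwandani,Interviewer 18,F,11.49,4.32,3.02,19.97
Viwandani,Interviewer 2,M,5.68,1.79,2.17,9.19
Viwandani,Interviewer 4,M,11.11,2.05,7.09,15.13
Viwandani,Interviewer 5,M,4.38,1.65,1.14,7.62
Viwandani,Interviewer 6,M,21.73,3.20,15.45,28.01
Viwandani,Interviewer 7,M,9.63,2.20,5.32,13.95
Viwandani,Interviewer 9,M,10.80,2.03,6.82,14.78
Viwandani,Interviewer 12,M,3.40,1.28,0.89,5.92
Viwandani,Interviewer 15,M,3.60,1.80,0.08,7.13
Korogocho,Interviewer 19,F,11.49,2.44,6.72,16.27
Korogocho,Interviewer 20,F,10.86,2.48,6.00,15.72
Korogocho,Interviewer 22,F,8.42,2.16,4.17,12.66
Korogocho,Interviewer 28,F,6.48,2.04,2.47,10.48
Korogocho,Interviewer 21,M,4.96,1.65,1.73,8.20
Korogocho,Interviewer 23,M,7.19,2.54,2.22,12.16
Korogocho,Interviewer 24,M,10.99,2.33,6.42,15.56
Korogocho,Interviewer 25,M,14.57,2.84,9.01,20.13
Korogocho,Interviewer 26,M,14.77,2.82,9.24,20.30
Korogocho,Interviewer 27,M,5.79,1.49,2.87,8.71
Korogocho,Interviewer 29,M,23.70,3.16,17.51,29.89
Korogocho,Interviewer 30,M,11.18,3.35,4.61,17.75
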