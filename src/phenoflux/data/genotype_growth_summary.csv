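genotype,genome,control_mean,control_se,stress_mean,stress_se,inhibition_printed_pct,significance
Figue Pomme Geante,AAB,40.95,4.38,29.11,2.02,28.9,*
Simili Radjah,ABB,53.45,3.92,27.62,1.83,48.3,***
Kluai Tiparot,ABB,43.87,3.45,27.44,2.3,37.5,**
Fougamou 1,ABB,40.34,2.38,26.14,3.21,35.2,**
Leite,AAA,44.3,4.85,25.4,4.44,42.7,*
Pisang Bakar,AAA,47.38,2.56,24.46,1.9,48.4,***
Blue Java,ABB,40.02,2.74,24.43,1.81,39,***
Namwa Khom,ABB,39.75,2.22,23.79,1.83,40.1,***
Pisang Ceylan,AAB,36.2,2.96,23.48,1.91,35.1,**
Pisang Raja Bulu,AAB,32.76,1.45,21.94,1.49,33,***
Pelipita,ABB,29.9,1.75,19.59,1.48,34.5,***
Khai Thong Ruang,AAA,32.78,2.47,18.65,2.36,43.1,**
Pisang Rajah,AAB,27.67,1.68,18.44,2.18,33.3,**
Williams,AAA,31.5,4.97,18.44,4,41.5,nS
Saba,ABB,27.5,3.64,18.22,1.51,33.7,*
Red Dacca,AAA,39.7,3.99,18.14,4.58,54.3,**
Pisang Berangan,AAA,42.45,2.44,17.29,4.08,59.3,***
Monthan,ABB,24.3,3.87,16.86,2.96,30.6,nS
Gros Michel,AAA,40.92,3.67,16.29,2.2,60.2,***
Grande Naine,AAA,31.41,3.33,15.96,3.43,49.2,**
Uzakan,AAB,30.37,3.32,15.22,2.12,49.9,**
Pisang Klutuk Wulung,BB,24.86,2.52,13.85,2.34,44.3,**
Mbwazirume,AAA,21.8,1.33,13.44,1.36,38.3,***
Prata Ana,AAB,24.18,1.4,13.33,1.66,44.9,***
Banksii,AA,29.01,1.85,12.5,2.02,56.9,***
Pisang Palembang,AAB,21.57,2.21,12.17,2.54,43.6,*
Foconah,AAB,19.09,1.17,11.65,1.4,39,**
Dole,ABB,13.17,2.07,10.58,1.02,19.7,nS
Zebrina,AA,16.6,2.05,9.59,2.2,42.2,*
Orishele,AAB,7.32,1.14,6.55,1.67,10.5,nS
Poyo,AAA,13.3,1.91,4.64,1.03,65.1,**
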