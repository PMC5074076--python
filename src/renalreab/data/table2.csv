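drug,papp_1e6_cm_s,fu_p,clr_obs_ml_min,ion_class,logd74,logd65,pka_acid,pka_base,transporter
Antipyrine,124.9,0.89,1.22,Neutral,0.11,0.11,,,
Aprindine,31.8,0.05,1.28,Base,2.50,1.53,,9.95;5.85,
Atenolol,0.256,0.97,145,Base,-2.65,-3.55,,9.39,OCT2
Betamethasone,26.5,0.36,9.50,Neutral,1.99,1.99,,,P-gp
Betaxolol,20.0,0.45,49.6,Base,0.63,-0.27,,9.53,
Caffeine,81.12,0.67,1.06,Neutral,0.11,0.11,,,
Chlorpheniramine,28.5,0.30,26.2,Base,1.22,0.31,,9.35;5.15,
Chlorpropamide,88.12,0.05,0.56,Acid,-0.33,0.56,4.69,,
Citalopram,20.9,0.50,65.2,Base,1.55,0.65,,9.57,
Dapsone,49.7,0.27,5.50,Neutral,0.85,0.85,,,
Difloxacin,74.6,0.62,4.54,Zwitterion,0.70,0.70,5.81,7.39,
Doxepin,36.5,0.22,9.75,Base,2.23,1.41,,8.00,
Fluconazole,36.3,0.86,15.7,Neutral,0.46,0.46,,,P-gp
Gabapentin,0.67,0.97,95.1,Zwitterion,-1.10,-1.79,4.72,10.27,OCTN1
Grepafloxacin,110,0.61,47.6,Zwitterion,0.50,0.50,6.44,8.74,P-gp
Imipramine,33.4,0.13,6.80,Base,2.49,1.60,,9.17,
Irbesartan,44.0,0.05,2.37,Acid,1.29,2.19,3.91,,
Isoxicam,142,0.04,0.02,Acid,-0.20,0.70,3.84,,
Levetiracetam,15.7,0.90,39.4,Neutral,-0.63,-0.63,,,
Linezolid,36.1,0.78,39.5,Neutral,0.67,0.67,,,
Melagatran,0.145,0.93,114,Amphoteric,-1.42,-1.42,2.12,11.62;8.16,P-gp
Metoprolol,17.0,0.87,110,Base,-0.29,-1.19,,9.40,OCT2
Metronidazole,64.7,0.98,9.64,Neutral,-0.11,-0.11,,,
Mexiletine,43.8,0.48,71.6,Base,0.62,-0.27,,9.13,
Moclobemide,64.4,0.50,3.42,Base,1.60,1.34,,6.53,
Moxifloxacin,26.7,0.57,42.7,Zwitterion,-0.24,-0.24,6.31,9.51,P-gp;MRP2
Oxprenolol,29.95,0.14,9.35,Base,0.23,-0.67,,9.60,
Oxytetracycline,0.85,0.77,90.8,Zwitterion,-4.70,-4.70,3.27;7.32;9.11,10.80,P-gp
Pefloxacin,63.7,0.75,12.9,Zwitterion,0.30,0.35,6.28,7.55,P-gp
Prednisolone,19.7,0.32,34.3,Neutral,1.62,1.62,,,P-gp
Prednisone,37.3,0.45,37.9,Neutral,1.25,1.25,,,P-gp (weak)
Probenecid,84.5,0.09,0.50,Acid,-0.14,0.76,3.36,,
Propafenone,26.4,0.08,7.37,Base,1.72,0.82,,9.62,
Propylthiouracil,80.8,0.16,3.20,Neutral,0.70,0.78,8.01,,
Ribavirin,1.55,1.00,109.9,Neutral,-2.14,-2.14,,,
Ropivacaine,32.3,0.05,2.73,Base,2.10,1.27,,8.10,
Sparfloxacin,49.83,0.67,21.7,Zwitterion,-0.15,-0.91,6.31,8.94,P-gp
Sulfamethoxazole,41.7,0.35,4.52,Acid,-0.63,0.20,5.81,,
Tetracycline,1.10,0.76,86.4,Zwitterion,-0.90,-0.90,5.06;7.63;8.77,10.52,OAT3 (weak)
Theophylline,65.13,0.52,5.50,Neutral,-0.09,-0.06,8.51,,
Tocainide,19.0,0.69,67.5,Base,0.03,-0.73,,7.75,
Topiramate,46.2,0.87,15.1,Neutral,0.60,0.61,9.22,,MATE2K
Venlafaxine,27.6,0.73,80.0,Base,0.95,0.05,,9.64,
Verapamil,20.9,0.16,25.6,Base,2.61,1.73,,8.74,P-gp;OCTN1;OCTN2
Voriconazole,96.51,0.42,1.57,Neutral,1.70,1.70,,,
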