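name,logp,pka1,pka1_kind,pka2,pka2_kind,fup_ob,fup_pr,bp,caco2_ob,caco2_pr,clint_ob,clt_ob,clt_pr
Acetaminophen,0.91,9.46,a,,,0.52,0.34,1.04,100,19.2,12.0,0.30,0.40
Alprazolam,3.02,5.01,b,,,0.29,0.17,0.78,25.5,51.7,1.37,0.04,0.12
Amitriptyline,4.81,9.76,b,,,0.07,0.07,0.86,54.7,23.1,14.6,0.37,0.78
Atenolol,0.43,9.67,b,,,0.94,0.58,1.12,1.60,1.00,12.0,0.15,0.36
Betaxolol,2.54,9.67,b,,,0.22,0.36,1.03,53.9,44.8,19.0,0.20,0.52
Bosentan,4.94,5.8,a,,,0.04,0.07,0.55,1.05,21.0,12.0,0.13,0.18
Caffeine,-0.07,,,,,0.64,0.46,1.00,40.1,33.6,0.33,0.08,0.11
Chlorpromazine,5.40,9.40,b,,,0.06,0.06,1.19,17.8,10.5,49.6,0.96,0.65
Cimetidine,-0.11,6.91,b,,,0.78,0.76,0.97,4.48,3.00,8.56,0.49,0.57
Clozapine,3.40,7.35,b,,,0.06,0.04,0.81,30.7,31.5,13.7,0.15,0.32
Desipramine,3.90,10.01,b,,,0.16,0.14,0.93,29.5,14.5,19.7,0.66,0.86
Dexamethasone,1.68,12.42,a,,,0.198,0.25,0.93,15.0,16.5,8.56,0.20,0.39
Diazepam,2.82,3.4,b,,,0.02,0.05,0.81,41.0,50.1,1.88,0.02,0.04
Diclofenac,4.26,4,a,,,0.01,0.004,0.60,20.2,39.8,177,0.21,0.13
Diltiazem,2.73,12.86,a,8.18,b,0.18,0.15,0.99,38.7,20.2,26.5,0.78,0.65
Furosemide,1.75,4.25,a,,,0.01,0.13,0.90,1.60,1.60,25.7,0.10,0.06
Ibuprofen,3.97,5.53,a,,,0.006,0.05,0.55,48.1,46.2,30.0,0.05,0.07
Imipramine,4.28,9.2,b,,,0.08,0.12,0.99,30.0,13.2,27.4,0.78,0.88
Ketoprofen,3.10,4.45,a,,,0.008,0.01,1.09,40.3,48.3,6.93,0.10,0.04
Lidocaine,2.84,7.75,b,,,0.33,0.28,0.74,18.5,21.5,15.9,0.96,0.65
Methylprednisolone,1.80,,,,,0.23,0.17,0.88,9.59,11.8,24.0,0.37,0.35
Metoprolol,1.76,9.67,b,,,0.88,0.61,1.15,34.2,12.3,3.68,0.78,0.58
Midazolam,2.90,6.19,b,,,0.02,0.04,0.68,39.8,42.6,302,0.32,0.11
Montelukast,8.49,4.40,a,3.12,b,0.002,0.003,0.55,76.0,5.20,96.3,0.04,0.15
Morphine,0.89,8.21,b,,,0.65,0.57,1.00,6.27,10.2,64.6,1.56,1.23
Nadolol,0.81,9.76,b,,,0.14,0.65,1.00,1.17,2.90,17.1,0.17,0.33
Naloxone,1.67,10.07,a,7.84,b,0.54,0.49,1.43,21.5,21.9,12.0,1.38,1.18
Naproxen,3.18,4.15,a,,,0.002,0.01,0.51,52.8,41.9,18.0,0.004,0.02
Nifedipine,2.20,,,,,0.04,0.04,0.74,42.0,29.0,82.2,0.44,0.81
Omeprazole,2.23,4.47,b,9.29,a,0.05,0.03,0.61,54.8,12.4,15.4,0.50,0.17
Ondansetron,2.80,7.34,b,,,0.27,0.24,0.79,110,107,2.57,0.35,0.20
Prazosin,1.30,6.54,b,,,0.06,0.15,0.70,7.72,10.8,6.93,0.28,0.25
Propranolol,2.58,9.67,b,,,0.13,0.17,0.89,45.0,31.8,18.8,0.72,0.56
Ranitidine,0.20,7.8,b,,,0.95,0.59,1.00,4.45,0.70,3,0.58,0.34
Quinidine,2.51,9.05,b,,,0.26,0.09,1.02,21.0,5.70,21.4,0.24,0.43
Sildenafil,1.87,11.14,a,5.59,b,0.04,0.06,0.81,55.0,43.9,51.4,0.54,0.49
Theophylline,-0.02,8.81,a,,,0.61,0.34,0.92,44.1,14.5,2.65,0.05,0.19
Triazolam,3.63,4.26,b,,,0.10,0.16,0.62,28.0,29.9,43.5,0.18,0.11
Verapamil,3.79,8.92,b,,,0.09,0.14,0.81,79.0,24.3,122,1.08,0.58
Vinorelbine,4.80,8.66,b,,,0.87,0.09,0.58,1.30,2.90,108,1.20,0.47
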