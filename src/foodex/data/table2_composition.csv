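name,food_class,moisture,ash,cho,protein,fat,energy,dv_cho,dv_protein,dv_fat,dv_energy,flags
Baba ghanouj,dish,91.5,1.1,4.5,1.1,1.8,39,1.6,2.2,2.3,1.9,
Batata mehchi,dish,69.5,1.8,18,5,5.7,143,6.5,10,7.3,7.1,
Borgul bi banadoura,dish,69.1,1.5,20.8,3,5.6,146,7.5,6,7.1,7.3,
Chichbarak,dish,68.1,1.7,18.7,4.8,6.7,154,6.8,9.6,8.5,7.7,
Falafel,dish,31.3,3.4,36.5,13.3,15.6,339,13.2,26.6,20,16.9,
Fatayer sbanikh,dish,45,2.4,27.2,5.3,20.1,311,9.8,10.6,25.7,15.5,
Fattat hommos,dish,68.7,1.3,15.8,6.5,7.7,159,5.7,13,9.8,7.9,
Fattoush,dish,88.1,1.3,7.2,1.5,1.9,52,2.6,3,2.4,2.6,
Foul moudamas,dish,75.3,1,14.2,5.3,4.2,116,5.1,10.6,5.3,5.8,
Hindbe bi zet,dish,67.7,1.5,5.9,2.5,22.4,235,2.1,5,28.7,11.7,
Hommos bi tahini,dish,68.2,1.9,17.2,7.5,5.2,146,6.2,15,6.6,7.3,
Kafta wa batata,dish,79.3,1.5,7,8.8,3.4,94,2.5,17.6,4.3,4.7,
Kibba bi sayniya,dish,51.4,1.8,19.7,11.3,15.8,266,7.1,22.6,20.2,13.3,
Koussa mehchi,dish,71.6,1.4,20.3,3.8,2.9,123,7.3,7.6,3.7,6.1,
Lahm bi ajeen,dish,44.6,1.5,37.1,11.2,5.6,244,13.4,22.4,7.1,12.2,
Loubia bi zet,dish,86.5,1.4,7.2,2.1,2.8,62,2.6,4.2,3.5,3.1,
Malfouf mehchi,dish,81.5,1.3,12.1,3.8,1.3,75,4.4,7.6,1.6,3.7,
Moujadara,dish,71.1,1.2,21.8,5.4,0.5,113,7.9,10.8,0.6,5.6,
Moghrabia,dish,72.8,1,15.6,6.7,3.9,124,5.6,13.4,5,6.2,
Mousaka batinjen,dish,70.6,1.1,14.8,3.2,10.3,165,5.3,6.4,13.2,8.2,
Riz a dajaj,dish,65.4,1.6,18.8,7.2,7,167,6.8,14.4,8.9,8.3,
Riz bi lahma,dish,63,1.7,23,7.5,4.8,165,8.3,15,6.1,8.2,
Sayadiah,dish,64.2,0.9,22.1,6.5,6.3,171,8,13,8,8.5,
Shawarma dajaj,dish,58.6,2.4,1.1,29.7,8.2,197,0.4,59.4,10.5,9.8,
Shawarma lahma,dish,67.3,1.6,2.6,17.5,11,179,0.9,35,14.1,8.9,
Tabboula,dish,88.3,1.4,6.1,1.9,2.3,53,2.2,3.8,2.9,2.6,
Warak enab,dish,75.1,1.3,17.7,4.4,1.5,102,6.4,8.8,1.9,5.1,
Yakhnet Bamia,dish,73.5,1.3,17,3.9,4.3,122,6.1,7.8,5.5,6.1,
Yakhnet Fassoulia,dish,66.3,1.1,22.6,8.1,1.9,140,8.2,16.2,2.4,7,
Yakhnet Mouloukhia,dish,76.3,1.6,11.9,5.4,4.8,112,4.3,10.8,6.1,5.6,
Baklava mixed,sweet,7,1.1,64,6.6,27.3,474,23.2,13.2,28,23.7,
Baklava mixed light,sweet,7.6,1,61.9,7.1,28.7,478,22.5,14.2,29.4,23.9,
Barazik,sweet,1.5,1.3,49,15.3,42.1,553,17.8,30.6,43.2,27.7,
Boundoukia,sweet,4.8,1.5,64.1,11.5,23.2,465,23.3,23,23.8,23.3,
Daoukia,sweet,27.4,0.7,52.8,7.3,15.1,347,19.2,14.6,15.5,17.4,
Foustoukia,sweet,4.8,1.8,59.7,19.2,18.5,446,21.7,38.4,19,22.3,
Ghourayba,sweet,4.2,0.4,62.9,6.8,32.9,510,22.8,13.6,33.8,25.5,
Halawa,sweet,3.8,1.7,45.7,16.8,41,538,16.6,33.6,42.1,26.9,
Halawa light,sweet,0.7,1.4,57.5,12.6,35.6,531,20.9,25.2,36.5,26.6,
Halawet El Jiben,sweet,45.4,1.3,36.7,9.7,8.8,248,13.3,19.4,9,12.4,
Ish el bulbul,sweet,5.2,1,65.8,7.5,26.2,478,23.9,15,26.9,23.9,
kallaj kashta,sweet,55,0.8,33,3.6,9.7,215,12,7.2,10,10.8,
karabij joz maa crema,sweet,17.8,0.6,61.1,7.6,16.5,391,22.2,15.2,16.9,19.6,
katayef kashta,sweet,44.5,0.8,40.5,6,10.5,260,14.7,12,10.7,13,
kounafa kashta bil kaak,sweet,42,0.9,42.2,8.1,8.7,262,15.3,16.2,8.9,13.1,
Kounafa bil jiben,sweet,42.6,0.6,40.4,6.1,13.2,279,14.6,12.2,13.5,14,
Maakroun and moushabbak,sweet,5.2,0.2,77.1,3.5,17.9,448,28,7,18.4,22.4,
Maamoul tamer,sweet,11.8,1,68.4,6.6,15.6,410,24.8,13.2,16,20.5,
Maamoul mad kashta,sweet,37.2,0.9,49.6,5.3,8.9,283,18,10.6,9.2,14.2,
Maamoul mad joz,sweet,12.9,0.8,58.8,8,25,443,21.3,16,25.6,22.2,
Maamoul fostok,sweet,14.5,0.8,53.3,10.4,26.9,444,19.3,20.8,27.6,22.2,
Maamoul joz,sweet,8.9,0.6,66.2,10,18.3,433,24,20,18.8,21.7,
Madlouka,sweet,29.36,1.1,51.1,8,13,328,18.5,16,13.4,16.4,
Mafrouka kashta,sweet,10.1,0.8,71.1,4.3,17.5,425,25.8,8.6,18,21.3,
Moufattaka,sweet,26.3,0.7,59.2,5.9,10.1,332,21.5,11.8,10.3,16.6,
Mouhallabiya,sweet,55.4,1.1,31.6,6.2,7.3,203,11.4,12.4,7.5,10.2,
Moushabak,sweet,13.5,0.1,71.5,2.1,16.4,410,26,4.2,16.8,20.5,ash_censored_below_0.1
Nammoura,sweet,14.3,0.4,75.4,3,8.8,376,27.4,6,9,18.8,
Osmaliya,sweet,48.4,1.3,27,9.3,17.9,271,9.8,18.6,18.4,13.6,
Riz bil halib,sweet,54.2,1.3,32.7,6.7,6.5,204,11.8,13.4,6.7,10.2,
Saniora,sweet,2.3,1,68.7,7.4,26.4,490,24.9,14.8,27.1,24.5,
Sfouf,sweet,20.6,0.7,55.2,6.3,22,401,20,12.6,22.6,20.1,
Shaaybiyat,sweet,39.4,0.5,39.1,9.5,14.7,298,14.2,19,15.1,14.9,
Ward el sham,sweet,46.9,1.2,34.4,8.2,11.9,254,12.5,16.4,12.2,12.7,
Znoud el sitt,sweet,40.3,0.3,41,4.5,17.8,307,14.9,9,18.2,15.4,
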