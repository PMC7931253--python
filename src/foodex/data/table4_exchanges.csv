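name,food_class,exchanges_100g,serving_text,exchanges_serving,cho,protein,fat,energy,flags
Baba ghanouj,dish,"1 vegetable, 0.25 fat",100 g (6 Tbsp),"1 vegetable, 0.25 fat",4.5,1.1,1.8,39,
Batata mehchi,dish,"1,25 starch, 1 fat",100 g (1 Large or 3 small),"1,25 starch, 1 fat",18,5,5.7,143,
Borgol bi banadoura,dish,"1,5 starch, 0.5 fat",100 g (1/2 cup),"1,5 starch, 0.5 fat",20.8,3,5.6,146,
Chichbarak,dish,"1 starch, 0.5 WM",100 g (1/2 cup),"1 starch, 0.5 WM",18.7,4.8,6.7,154,
Falafel,dish,"2 starch, 2 MFM, 0.5 fat",40 g (2 patty balls),"1 starch, 1 MFM",14.6,5.3,6.2,135.6,
Fatayer sbanikh,dish,"1.5 starch, 1 protein, 4 fat",55 g (1 triangle),"1 starch, 2 fat",14.9,2.9,11.0,171.0,
Fattat hommos,dish,1 whole milk,100 g (1/2 cup),1 WM,15.8,6.5,7.7,159,
Fattoush,dish,"1 vegetable, 0.5 fat",200 g (1 cup),"2 vegetable, 1 fat",14.4,3,3.8,104,
Foul moudamas,dish,"1 starch, 1 LM",100 g (1/2 cup),"1 starch, 1 LM",14.2,5.3,4.2,116,
Hindbe bil zet,dish,"1 vegetable, 4,5 fat",50 g (1/4 cup),"0.5 vegetable, 2 fat",2.9,1.2,11.2,117.5,
Hommos bi tahini,dish,"1 starch, 1 MFM",100 g (6 Tbsp),"1 starch, 1 MFM",17.2,7.5,5.2,146,
Kafta wa batata,dish,"0.5 starch, 1 LM, 0.25 fat",200 g (1 cup),"1 starch, 2 LM, 0.25 fat",14,17.6,6.8,188,
Kibba bi sayniya,dish,"1,25 starch, 1,5 HFM",76 g (half a square),"1 starch, 1 HFM, 0.5 fat",14.9,8.5,12.0,202.1,
Koussa mehchi,dish,"1 starch, 1 vegetable, 0.5 fat",100 g (2 Medium),"1 starch, 1 vegetable, 0.5 fat",20.3,3.8,2.9,123,
Lahm bi ajeen,dish,"2,5 starch, 1 LM",40 g (2 medium piece),"1 starch, 0.5 LM",14.8,4.4,2.24,97.6,
Loubi bil zet,dish,"1,5 vegetable, 0.5 fat",100 g (1/2 cup),"1.5 vegetable, 0.5 fat",7.2,2.1,2.8,62,
Malfouf mehchi,dish,"1 vegetable, 0.5 starch",100 g (4 pieces),"1 vegetable, 0.5 starch",12.1,3.8,1.3,75,
Moujadara,dish,"1 starch, 0.5 LM",100 g (1/2 cup),"1 starch, 0.5 LM",21.8,5.4,0.5,113,
Moghrabia,dish,"1 starch, 1 LM",100 g (1/2 cup),"1 starch, 1 LM",15.6,6.7,3.9,124,
Mousaka batinjan,dish,"1 starch, 2 fat",100 g (1/2 cup),"1 starch, 2 fat",14.8,3.2,10.3,165,
Riz a dajaj,dish,"1 starch, 1LM, 1 fat",100 g (1/2 cup),"1 starch, 1 LM, 1 fat",18.8,7.2,7,167,
Riz bi lahma,dish,"1 starch, 1 LM, 1 fat",65 g (1/3 cup),"1 starch, 0.5 LM",14.9,4.8,3.1,107.2,
Sayadia,dish,"1, 25 starch, 1 MFM",100 g (1/2 cup),"1, 25 starch, 1 MFM",22.1,6.5,6.3,171,
Shawarma dajaj,dish,"4,25 LM",54 g (4 Tbsp),"2 LM,0.25 fat",0.5,16.0,4.4,106.3,
Shawarma lahma,dish,"2,25 MF, 0.25 fat",50 g (4 Tbsp),"1 MF, 0.25 fat",1.3,8.7,5.5,89.5,
Tabboula,dish,"1 vegetable, 0.5 fat",200 g (1 cup),"2 vegetable, 1 fat",12.2,3.8,4.6,106,
Warak enab,dish,"1 vegetable,1 starch",100 g (6 pieces),"1 vegetable,1 starch",17.7,4.4,1.5,102,
Yakhnet bamia,dish,"0.5 starch, 2 vegetable, 1 fat",100 g (1/2 cup),"0.5 starch, 2 vegetable, 1 fat",17,3.9,4.3,122,
Yakhnet fassoulia,dish,"1,5 starch, 1 LM",100 g (1/2 cup),"1,5 starch, 1 LM",22.6,8.1,1.9,140,
Yakhnet mouloukhia,dish,"2 vegetable, 0.5 LM, 1 fat",100 g (1/2 cup),"2 vegetable, 0.5 LM, 1 fat",11.9,5.4,4.8,112,
Baklava mixed,sweet,"3 starch, 1 sugar, 4 fat",23 (1 piece),"1 starch, 1 fat",14.7,1.51,4.8,109,fat_backcomputed
Baklava mixed light,sweet,"3,25 starch, 4 fat, 0.5 sugar",24 (1 piece),"1 starch, 1 fat",14.8,1.7,5.3,114,fat_backcomputed
Barazik,sweet,"3 starch, 1 LM, 6 fat",30 (1 piece),"1 starch, 2 fat",14.7,4.5,9.8,165,fat_backcomputed|serving_rounding_deviation
Boundoukia,sweet,"3 starch,1 LM, 3 fat, 1 sugar",23 (1 medium bar),"1 starch, 1 fat",14.7,2.6,4.1,106,fat_backcomputed
Daoukia,sweet,"2.5 starch, 1 RFM, 1 fat",28 (1 small piece),"1 starch, 0.5 fat",14.7,2,3.3,97,fat_backcomputed
Foustoukia,sweet,"4 starch, 1 LM, 2 fat",25 (1 medium bar),"1 starch, 1 fat",14.9,4.8,3.6,111,fat_backcomputed
Ghourayba,sweet,"3 starch, 1 sugar, 5 fat",24 (2 pieces),"1 starch, 1 fat",15,1.6,6.1,117,fat_backcomputed
Halawa,sweet,"3 starch, 1 LM, 6 fat",33 (2 Tbsp),"1 starch, 2 fat",15,5.5,10.5,172,fat_backcomputed
Halawa light,sweet,"4 starch, 5 fat",26 (1.5 Tbsp),"1 starch, 1,5 fat",14.9,3.2,7.2,138,fat_backcomputed
Halawet el Jiben,sweet,"1 starch, 1 RFM, 1 sugar",41 (2 medium pieces or 1 large piece),"1 starch, 0.25RFM",15,3.9,2.8,99,fat_backcomputed
Ish el bulbul,sweet,"3 starch, 1 sugar, 4 fat",23 (1 piece),"1 starch, 0.5 fat",15.1,1.7,4.7,105,fat_backcomputed
kallaj kashta,sweet,"2 starch, 1.5 fat",45 (1 large piece),"1 starch, 0.5 fat",14.8,1.6,3.4,96,fat_backcomputed
karabij joz maa crema,sweet,"4 starch, 1 LM, 1 fat",24 (2 pieces),"1 starch, 0.5 fat",14.6,1.8,3,93,fat_backcomputed|serving_rounding_deviation
katayef Kashta,sweet,"2 starch, 1 HFM",37 (1 small piece),"1 starch, 0.5 fat",14.9,2.2,3,96,fat_backcomputed
kounafa kashta bil kaak,sweet,"1.75 starch, 1 RFM",35 (1 small piece or 2 Tbsp),"1 starch, 0.25 fat",14.7,2.8,2.3,91,fat_backcomputed|serving_rounding_deviation
Kounafa bil jibn,sweet,"2 starch, 1 MFM, 1 fat",37 (1 small piece or 2 Tbsp),"1 starch, 0.5 fat",14.9,2.2,3.8,103,fat_backcomputed
Maakroun and moushabbak,sweet,"3 starch, 2 fat, 2 sugar",19 (1 small piece from each one),1 starch,14.6,0.6,2.6,85,fat_backcomputed
Maamoul tamer,sweet,"3 starch, 2 fat, 1 sugar",22 (2 small pieces),"1 starch, 0.5 fat",15,1.4,2.6,90,fat_backcomputed
Maamoul mad kashta,sweet,"3 starch, 1 fat",30 (1 small piece),1 starch,14.8,1.5,2.1,85,fat_backcomputed
Maamoul mad joz,sweet,"2,5 starch, 1 sugar, 4 fat",25 (1 small piece),"1 starch, 1 fat",14.7,2,4.8,110,fat_backcomputed|serving_rounding_deviation
Maamoul fostok,sweet,"3,5 starch, 4 fat",28 (1 small piece),"1 starch, 1 fat",14.9,2.9,5.8,124,fat_backcomputed
Maamoul joz,sweet,"3 starch, 2.5 fat, 1 sugar",22 (1 small piece),"1 starch, 0.5 fat",14.5,2.2,3.1,95,fat_backcomputed|serving_rounding_deviation
Madlouka,sweet,"2.25 starch, 1 WM",29 (2 Tbsp),"1 starch, 0.5 fat",14.8,2.3,2.9,95,fat_backcomputed
Mafrouka kashta,sweet,"3,5 starch, 1 sugar, 2 fat",21 (1.5 Tbsp),1 starch,14.9,0.9,2.8,89,fat_backcomputed
Moufattaka,sweet,"2 starch, 2 sugar, 1 fat",25 (1.5 Tbsp),1 starch,14.8,1.4,1.9,83,fat_backcomputed
Mouhallabiya,sweet,"1 other CHO, 1 RFM, 0.5 sugar",47 (3Tbsp),"1 other-CHO, 0.25 RFM",14.8,2.9,2.6,95,fat_backcomputed
Moushabak,sweet,"2.5 starch, 2 fat, 2 sugar",21 (1 large piece),1 starch,15,0.4,2.6,82,fat_backcomputed
Nammoura,sweet,"3 starch, 0.25 fat, 2 sugar",20 (1 small piece),1 starch,15,0.6,1.3,75,fat_backcomputed
Osmaliya,sweet,"1 starch, 1 WM, 1 fat",55 (1 medium piece),"1 starch, 1 fat",14.8,5.1,7.7,149,fat_backcomputed|serving_rounding_deviation
Riz bil Halib,sweet,"1 other-CHO, 1 RFM, 0.5 sugar",46 (3Tbsp),"1 other-CHO, 0.25 RFM",15,3,2.3,92,fat_backcomputed
Saniora,sweet,"3 starch, 1,25 sugar, 4 fat",22 (1 medium piece),"1 starch, 1 fat",15.1,1.6,4.5,107,fat_backcomputed
Sfouf,sweet,"3,25 starch, 3 fat",27 (1 small piece),"1 starch, 1 fat",14.9,1.7,4.6,108,fat_backcomputed
Shaaybiyat,sweet,"1.5 starch, 1 RFM, 1,5 fat",38 (1 small piece),"1 starch, 0.5 RFM",14.8,3.6,4.3,113,fat_backcomputed
Ward el sham,sweet,"1.25 starch, 1 WM",44 (1 medium piece),"1 starch, 0.5 fat",15.1,3.6,4,109,fat_backcomputed
Znoud el sitt,sweet,"2,5 starch, 2.5 fat",36 (1 medium piece),"1 starch, 1 fat",14.7,1.6,5,110,fat_backcomputed|serving_rounding_deviation
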