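genotype,eurolegume_number,accession,local_name,country,donor
Estonia1,P58,EST2882,Eesti hall,Estonia,ECRI
Estonia2,P56,EST894,Eesti kollane söögihernes,Estonia,ECRI
Estonia3,P61,EST37,Jõgeva kirju,Estonia,ECRI
Estonia4,P65,EST41,Seko,Estonia,ECRI
Latvia1,P02,,Alma,Latvia,SPPBI
Latvia2,P48,,Bruno,Latvia,SPPBI
Latvia3,P12,,k-4833 Stendes Hero,Latvia,SPPBI
Latvia4,P03,,Retrija,Latvia,SPPBI
Norway1,P79,NGB10778,Aslaug,Norway,NordGen
Norway2,P82,NGB20045,Onkel Niels,Norway,NordGen
Portugal1,P53,,Gp 3263,Portugal,INIAV
Portugal2,P51,,Gp 3491,Portugal,INIAV
Portugal3,P52,,Gp 3497,Portugal,INIAV
Portugal4,P54,,Grisel,Portugal,INIAV
Sweden1,P90,NGB 102513,Svalöf Butter,Sweden,JTI
Sweden2,P88,NGB 13138,Odalett,Sweden,JTI
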