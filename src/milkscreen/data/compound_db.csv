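name,class,formula,adduct,rt_min,precursor_mz,fragment1_mz,fragment2_mz,nce,mrl_ug_kg,stc_ug_kg,cv_r_pct
Amoxicillin,penicillin,C16H19N3O5S,[M+H]+,7.22,366.1118,208.0,349.1,10,4,4,9.7
Ampicillin,penicillin,C16H19N3O4S,[M+H]+,11.02,350.1169,106.1,192.0,20,4,4,7.1
Cloxacillin,penicillin,C19H18ClN3O5S,[M+H]+,17.24,436.0728,277.0,160.0,10,30,15,3.6
Dicloxacillin,penicillin,C19H17Cl2N3O5S,[M+H]+,17.89,470.0339,160.0,311.0,15,30,15,6.6
Nafcillin,penicillin,C21H22N2O5S,[M+H]+,17.95,415.1322,199.1,256.1,20,30,15,7.0
Oxacillin,penicillin,C19H19N3O5S,[M+H]+,16.91,402.1118,160.0,243.1,15,30,15,4.9
Penicillin G,penicillin,C16H18N2O4S,[M+Na]+,15.90,357.0882,160.0,176.1,10,4,4,14.2
Penicillin V,penicillin,C16H18N2O5S,[M+Na]+,16.93,373.0829,160.0,192.1,15,4,4,16.2
Cefalexin,cephalosporin,C16H17N3O4S,[M+H]+,10.37,348.1013,158.0,174.1,40,100,25,7.1
Cefazolin,cephalosporin,C14H14N8O4S3,[M+H]+,10.80,455.0373,156.0,153.0,15,50,25,4.5
Cefapirin,cephalosporin,C17H17N3O6S2,[M+H]+,8.08,424.0632,152.0,292.1,25,60,25,6.3
Cefquinome,cephalosporin,C23H24N6O5S2,[M+2H]2+,8.66,265.0695,134.1,324.1,16,20,10,11.2
Cefoperazone,cephalosporin,C25H27N9O8S2,[M+H]+,11.37,646.1497,143.1,290.1,16,50,25,4.3
Ceftiofur,cephalosporin,C19H17N5O7S3,[M+H]+,13.84,524.0363,241.0,210.0,25,100,50,5.1
Chlortetracycline,tetracycline,C22H23ClN2O8,[M+H]+,12.55,479.1216,444.1,154.0,26,100,50,4.9
Doxycycline,tetracycline,C22H24N2O8,[M+H]+,14.21,445.1621,428.1,410.1,30,100,50,8.3
Oxytetracycline,tetracycline,C22H24N2O9,[M+H]+,10.53,461.1555,426.1,337.1,30,100,50,7.8
Tetracycline,tetracycline,C22H24N2O8,[M+H]+,10.27,445.1605,154.0,410.1,30,100,50,5.3
Epi-Chlortetracycline,tetracycline,C22H23ClN2O8,[M+H]+,11.58,479.1216,444.1,154.0,26,100,50,3.3
Epi-Doxycycline,tetracycline,C22H24N2O8,[M+H]+,13.57,445.1605,428.1,410.1,30,100,50,2.7
Epi-Oxytetracycline,tetracycline,C22H24N2O9,[M+H]+,10.07,461.1555,426.1,201.1,30,100,50,5.6
Epi-Tetracycline,tetracycline,C22H24N2O8,[M+H]+,9.38,445.1605,410.1,392.1,30,100,50,3.7
Tiamulin,pleuromutilin,C28H47NO4S,[M+H]+,15.70,494.3299,192.1,119.0,30,,10,6.7
Valnemulin,pleuromutilin,C31H52N2O5S,[M+H]+,17.62,565.3670,263.1,164.1,30,,10,11.5
Tilmicosin,macrolide,C46H80N2O13,[M+2H]2+,13.94,435.2903,174.1,696.5,32,,20,7.0
Tylosin,macrolide,C46H77NO17,[M+H]+,15.93,916.5264,174.1,101.1,25,50,20,8.6
Azithromycin,macrolide,C38H72N2O12,[M+H]+,13.05,749.5171,158.1,83.0,28,50,20,2.9
Erythromycin,macrolide,C37H67NO13,[M+H]+,16.14,734.4685,158.1,83.0,20,40,20,4.4
Spiramycin,macrolide,C43H74N2O14,[M+2H]2+,12.48,422.2643,540.3,699.4,30,200,20,4.3
Clindamycin,lincosamide,C18H33ClN2O5S,[M+H]+,14.46,425.1872,126.1,377.2,30,150,75,4.8
Lincomycin,lincosamide,C18H34N2O6S,[M+H]+,9.17,407.2210,126.1,359.2,30,,75,4.2
Nalidixic Acid,quinolone,C12H12N2O3,[M+H]+,15.51,233.0921,205.1,159.1,70,,15,10.9
Oxolinic Acid,quinolone,C13H11NO5,[M+H]+,13.86,262.0710,160.0,234.0,80,,15,5.1
Ciprofloxacin,quinolone,C17H18FN3O3,[M+H]+,10.60,332.1405,231.1,203.1,65,100,15,4.7
Danofloxacin,quinolone,C19H20FN3O3,[M+H]+,10.75,358.1562,82.1,255.1,70,30,15,4.1
Difloxacin,quinolone,C21H19F2N3O3,[M+H]+,11.03,400.1467,299.1,58.1,65,,15,6.0
Enrofloxacin,quinolone,C19H22FN3O3,[M+H]+,10.66,360.1718,203.1,245.1,60,100,15,4.5
Flumequin,quinolone,C14H12FNO3,[M+H]+,16.01,262.0874,238.1,220.0,80,50,15,6.4
Marbofloxacin,quinolone,C17H19FN4O4,[M+H]+,9.54,363.1463,72.1,320.1,25,75,15,5.1
Norfloxacin,quinolone,C16H18FN3O3,[M+H]+,10.40,320.1405,231.1,203.1,80,,15,6.5
Ofloxacin,quinolone,C18H20FN3O4,[M+H]+,10.07,362.1511,261.1,221.1,50,,15,5.9
Sarafloxacin,quinolone,C20H17F2N3O3,[M+H]+,11.34,386.1311,299.1,338.1,60,,15,3.4
Sulfaquinoxaline,sulfonamide,C14H12N4O2S,[M+H]+,13.56,301.0754,156.0,108.0,38,100,50,6.2
Sulfachloropyridazine,sulfonamide,C10H9ClN4O2S,[M+H]+,10.75,285.0208,156.0,108.0,35,100,50,4.9
Sulfadiazine,sulfonamide,C10H10N4O2S,[M+H]+,7.39,251.0597,156.0,108.0,35,100,50,6.4
Sulfadimethoxin,sulfonamide,C12H14N4O4S,[M+H]+,13.16,311.0809,156.1,108.0,42,100,50,7.7
Sulfaguanidine,sulfonamide,C7H10N4O2S,[M+H]+,3.21,215.0597,156.0,108.0,40,100,50,18.5
Sulfamerazine,sulfonamide,C11H12N4O2S,[M+Na]+,8.69,287.0573,156.0,190.0,42,100,50,6.4
Sulfametazine,sulfonamide,C12H14N4O2S,[M+H]+,9.80,279.0910,124.1,156.0,42,100,50,6.0
Sulfamethizole,sulfonamide,C9H10N4O2S2,[M+H]+,9.78,271.0318,156.0,108.0,40,100,50,5.7
Sulfamethoxazole,sulfonamide,C10H11N3O3S,[M+H]+,10.91,254.0594,156.0,108.0,40,100,50,5.0
Sulfamethoxipyridazine,sulfonamide,C11H12N4O3S,[M+H]+,10.20,281.0703,126.1,108.0,50,100,50,3.2
Sulfamonomethoxin,sulfonamide,C11H12N4O3S,[M+H]+,11.17,281.0710,156.0,108.0,41,100,50,3.5
Sulfanilamide,sulfonamide,C6H8N2O2S,[M+H-NH3]+,3.65,156.0114,65.0,92.0,70,100,50,6.2
Sulfapyridin,sulfonamide,C11H11N3O2S,[M+H]+,8.27,250.0645,156.0,184.1,43,100,50,3.5
Sulfathiazole,sulfonamide,C9H9N3O2S2,[M+H]+,7.97,256.0209,156.0,108.0,38,100,50,3.9
Trimethoprim,sulfonamide,C14H18N4O3,[M+H]+,9.37,291.1452,123.1,261.1,60,50,50,7.1
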