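hospital,year,physicians_employed,physicians_contract,nurses_employed,nurses_contract,other_medical_staff,beds,acute_beds,hospitalisations,avg_length_of_stay,surgical_procedures,bed_occupancy,net_revenue,operating_costs,amortization,materials_energy,external_services,salaries_wages,civil_law_salaries,other_operating_revenue,grants,other_operating_expenses,financial_revenue,financial_costs,profit_on_sales,operating_profit,gross_result,net_result
BIA,2015,119,62,485,46,456,641,20,24505,6.5,,67,105910,117495,7521,25079,30578,53010,17153,8076,5383,577,41,1953,13459,1934,22,22
BIA,2016,113,46,489,58,479,641,20,25528,5.8,,68,112168,127951,9750,27957,32925,56050,19158,10817,5961,268,346,1644,-15141,-15141,18,18
BIA,2017,98,92,483,106,498,641,25,25306,5.7,,67,124173,143616,10776,30534,37258,63891,23671,11490,6981,487,42,1760,-18672,-18672,-4650,-4650
BIA,2018,99,121,488,121,490,642,25,24068,6.0,,62,138442,167304,10949,31564,47040,76501,31243,11462,9188,806,36,1770,-28841,-9139,-10873,-10873
BIA,2019,99,114,496,114,522,609,25,23297,5.5,,62,154296,193314,15612,34313,54241,87909,36299,17828,10911,1322,36,2676,-38994,-11778,-14418,-14418
BIA,2020,100,185,528,113,518,617,25,18944,6.0,,53,166863,212977,16982,36608,59158,98758,38175,34591,12341,1653,233,2564,-46107,-1068,-3399,-3399
BIA,2021,112,221,533,102,466,617,30,21207,5.8,,60,194042,261916,16964,42451,68407,132463,48563,50797,13655,3830,59,3244,-67867,-7257,-10442,-10442
BIA,2022,108,105,506,78,577,536,25,20126,5.7,,65,217710,270621,18488,43576,64817,141874,43782,26529,18694,4300,261,5796,-52897,-12204,-17739,-17739
BIA,2023,112,96,520,69,592,494,25,22636,5.1,,71,260233,306237,18415,49150,70121,166302,46919,20435,21671,5310,135,12571,-46004,-9200,-21636,-21636
BIA,2024,112,80,505,52,571,503,25,59398,8.2,,88,287530,340415,13589,49184,85868,189293,85868,15889,25562,22422,330,13135,-52885,-34751,-47556,-47556
LOM,2015,40,149,456,0,450,632,9,21562,5.4,,62,102964,102819,8252,23530,25704,43328,18454,757,6233,5304,42,528,1886,3572,3085,2926
LOM,2016,36,145,465,0,452,626,12,21688,5.2,,62,109798,109868,8197,25258,27549,46541,20035,3480,5667,2210,125,266,2134,2134,8931,8800
LOM,2017,30,139,470,0,605,626,12,21995,5.1,,63,112705,116136,7943,26969,25295,52438,20742,6848,4881,306,149,149,148,148,11576,10674
LOM,2018,30,139,474,20,632,631,12,20499,6.6,,58,124560,137755,7615,28148,32466,64591,27064,3987,5331,563,147,95,-11826,-11826,-3019,-3063
LOM,2019,31,157,478,26,643,496,10,19803,4.9,,68,132750,152746,9156,28783,34416,75567,28010,2601,6846,580,89,33,-16664,-16664,-8447,-8447
LOM,2020,31,157,454,30,623,528,10,9876,5.3,,34,164419,168759,10950,27156,42441,86366,33541,6872,6157,5998,65,50,-6776,-6776,941,907
LOM,2021,33,180,455,36,642,509,15,13133,5.1,,44,197541,217882,11615,41430,53983,108864,45333,8681,13087,1861,20,2,-19209,-19209,534,503
LOM,2022,37,188,468,34,662,489,11,17247,4.3,,51,198659,220433,10225,41211,55681,110856,46699,11417,10308,3350,401,1,-17840,-17840,244,209
LOM,2023,42,182,482,35,662,495,11,19212,4.0,,56,243113,260002,11051,48023,67978,130196,57432,3912,9866,1327,640,12,-16889,-5011,-4383,-4515
LOM,2024,40,179,557,40,675,506,11,15522,5.1,,57,274364,302638,11786,52946,81618,153178,81618,4336,9248,11295,136,105,-28273,-26919,-26888,-26888
SUW,2015,78,97,382,15,268,448,17,34545,3.2,,68,82766,90120,8260,18388,20057,39583,8564,2801,7291,3111,90,1071,-4063,1264,283,271
SUW,2016,73,133,400,16,287,448,17,35186,3.2,,68,91321,96586,7469,19659,22079,43309,9528,1586,5914,3291,35,838,-2273,-2273,1019,1015
SUW,2017,70,141,415,19,291,456,17,34948,3.0,,63,97525,106285,6669,22533,23781,48710,10210,2277,5619,2713,75,704,-3632,-3632,857,856
SUW,2018,73,96,425,48,311,456,17,36201,2.8,,61,113904,125037,6349,26581,27863,58773,13352,3398,5312,1732,41,697,-5726,1257,601,571
SUW,2019,65,95,422,68,315,423,17,35686,2.8,,65,133414,139795,7842,29620,31245,67063,15240,2672,7414,2400,39,663,-6385,1262,638,130
SUW,2020,60,90,421,68,322,423,17,28958,2.9,,55,144622,152921,9980,33717,36864,71152,20263,5040,10133,5299,17,562,-8299,1578,1033,1029
SUW,2021,56,106,411,90,345,418,17,32212,2.9,,60,176718,195247,10341,41258,49951,92464,29745,4945,10158,2040,12,361,-10655,-10655,534,2060
SUW,2022,69,158,413,99,332,414,17,33778,2.6,,59,182443,203144,11738,41966,52755,95586,28305,4139,11667,4353,176,733,-10292,-10292,607,603
SUW,2023,66,164,424,91,344,417,17,37617,2.3,,56,224366,236056,11373,51638,65148,106709,35718,2971,11373,1481,173,173,-11690,918,246,136
SUW,2024,58,122,425,122,289,417,17,38541,2.6,,67,257381,273677,10612,61826,80135,119833,80135,8389,10655,1877,152,152,-16296,887,104,104
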