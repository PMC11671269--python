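drug,median,q1,q3
verteporfin,396,114.5,1034
tacrolimus,334,107,966
hydroxychloroquine,259,80,512
sildenafil,164,14,746
mirabegron,163,51,900
tadalafil,153,8,424
brimonidine,152,63,511
sorafenib,150,14,651
celecoxib,142,35,159
bimatoprost,129,67.5,190.5
upadacitinib,113,61,230.25
anastrozole,100,14,695
vemurafenib,97.5,52,166.25
ponatinib,96,72,1021
rofecoxib,90,29.5,204
drospirenone,86,14,200
aripiprazole,74,11.5,566.5
vardenafil,71,10.5,165
dabrafenib,51,13,62
letrozole,37,13,103
estradiol,32,7,154
encorafenib,28,7,64
peginterferon beta-1a,17,7,151
fingolimod,4,3.75,120.5
raloxifene,1,1,8
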