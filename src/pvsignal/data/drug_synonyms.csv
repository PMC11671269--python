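verbatim,canonical
MYRBETRIQ,mirabegron
MIRABEGRON,mirabegron
EVISTA,raloxifene
RALOXIFENE,raloxifene
RALOXIFENE HCL,raloxifene
CIALIS,tadalafil
ADCIRCA,tadalafil
TADALAFIL,tadalafil
VIAGRA,sildenafil
REVATIO,sildenafil
SILDENAFIL,sildenafil
SILDENAFIL CITRATE,sildenafil
LEVITRA,vardenafil
VARDENAFIL,vardenafil
YASMIN,drospirenone
YAZ,drospirenone
DROSPIRENONE,drospirenone
ESTRACE,estradiol
ESTRADIOL,estradiol
LUMIGAN,bimatoprost
BIMATOPROST,bimatoprost
ALPHAGAN,brimonidine
BRIMONIDINE,brimonidine
BRIMONIDINE TARTRATE,brimonidine
VISUDYNE,verteporfin
VERTEPORFIN,verteporfin
ABILIFY,aripiprazole
ARIPIPRAZOLE,aripiprazole
CELEBREX,celecoxib
CELECOXIB,celecoxib
VIOXX,rofecoxib
ROFECOXIB,rofecoxib
GILENYA,fingolimod
FINGOLIMOD,fingolimod
NEXAVAR,sorafenib
SORAFENIB,sorafenib
ARIMIDEX,anastrozole
ANASTROZOLE,anastrozole
RINVOQ,upadacitinib
UPADACITINIB,upadacitinib
BRAFTOVI,encorafenib
ENCORAFENIB,encorafenib
ICLUSIG,ponatinib
PONATINIB,ponatinib
PLEGRIDY,peginterferon beta-1a
PEGINTERFERON BETA-1A,peginterferon beta-1a
FEMARA,letrozole
LETROZOLE,letrozole
ZELBORAF,vemurafenib
VEMURAFENIB,vemurafenib
TAFINLAR,dabrafenib
DABRAFENIB,dabrafenib
PROGRAF,tacrolimus
TACROLIMUS,tacrolimus
PLAQUENIL,hydroxychloroquine
HYDROXYCHLOROQUINE,hydroxychloroquine
HYDROXYCHLOROQUINE SULFATE,hydroxychloroquine
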