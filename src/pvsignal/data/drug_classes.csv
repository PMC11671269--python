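drug,atc_class,target_class
mirabegron,Urogenital System and Sex Hormone Drugs,Adrenergic Receptor Agonist
raloxifene,Urogenital System and Sex Hormone Drugs,Hormone Modulator
tadalafil,Urogenital System and Sex Hormone Drugs,PDE5 Inhibitor
sildenafil,Urogenital System and Sex Hormone Drugs,PDE5 Inhibitor
vardenafil,Urogenital System and Sex Hormone Drugs,PDE5 Inhibitor
drospirenone,Urogenital System and Sex Hormone Drugs,Hormone Modulator
estradiol,Urogenital System and Sex Hormone Drugs,Hormone Modulator
bimatoprost,Sensory Organ Drugs,Prostaglandin Analogue
brimonidine,Sensory Organ Drugs,Adrenergic Receptor Agonist
verteporfin,Sensory Organ Drugs,Photosensitizer
aripiprazole,Nervous System Drugs,Dopamine Partial Agonist
celecoxib,Musculoskeletal System Drugs,COX-2 Inhibitor
rofecoxib,Musculoskeletal System Drugs,COX-2 Inhibitor
fingolimod,Antitumor and Immunomodulating Drugs,S1P Receptor Modulator
sorafenib,Antitumor and Immunomodulating Drugs,Tyrosine Kinase Inhibitor
anastrozole,Antitumor and Immunomodulating Drugs,Hormone Modulator
upadacitinib,Antitumor and Immunomodulating Drugs,JAK Inhibitor
encorafenib,Antitumor and Immunomodulating Drugs,BRAF Inhibitor
ponatinib,Antitumor and Immunomodulating Drugs,Tyrosine Kinase Inhibitor
peginterferon beta-1a,Antitumor and Immunomodulating Drugs,Interferon
letrozole,Antitumor and Immunomodulating Drugs,Hormone Modulator
vemurafenib,Antitumor and Immunomodulating Drugs,BRAF Inhibitor
dabrafenib,Antitumor and Immunomodulating Drugs,BRAF Inhibitor
tacrolimus,Antitumor and Immunomodulating Drugs,Calcineurin Inhibitor
hydroxychloroquine,Antiparasitic Drugs,Antimalarial
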