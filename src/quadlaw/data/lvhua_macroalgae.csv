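species,abbrev,p,epsilon,delta
Jania pedunculata var. adhaerens,Jpa,0.0100,0.1976,0.3054
Alatocladia yessoensis,Ay,0.0150,0.0915,0.2213
Chondria crassicaulis,Cc,0.6000,-0.0881,0.1946
Grateloupia acuminata,Gac,0.0050,-0.0591,0.0110
Chondrus ocellatus,Coc,0.0050,-0.0591,0.0110
Chondrus nipponicus,Cn,0.2300,-0.1866,0.0795
Corallina officinalis,Cof,0.7500,0.1101,0.3792
Ahnfeltiopsis flabelliformis,Af,0.0050,-0.0591,0.0110
Gelidium amansii,Gam,0.0050,-0.0591,0.0110
Callophyllis adnata,Ca,0.0700,0.2155,0.4267
Chondracanthus intermedius,Ci,0.3600,-0.0881,0.1923
Petalonia binghamiae,Pb,0.0050,-0.0591,0.0110
Sargassum thunbergii,St,0.3650,0.0461,0.3268
Ishige okamurae,Io,0.1800,0.1027,0.3587
Ulva australis,Ua,0.7900,-0.1050,0.1574
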