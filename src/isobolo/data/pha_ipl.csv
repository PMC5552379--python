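# Dose-effect data: Pha1b intraplantar, capsaicin-induced nociception.
# Doses in nmol/site; response in %MPE; one row per animal.
regimen,dose,unit,response,subject_id
Pha1b i.pl.,0.01,nmol/site,19.51,pha_ipl-01
Pha1b i.pl.,0.01,nmol/site,27.44,pha_ipl-02
Pha1b i.pl.,0.01,nmol/site,46.34,pha_ipl-03
Pha1b i.pl.,0.01,nmol/site,0.33,pha_ipl-04
Pha1b i.pl.,0.01,nmol/site,6.23,pha_ipl-05
Pha1b i.pl.,0.01,nmol/site,-36.3,pha_ipl-06
Pha1b i.pl.,0.01,nmol/site,20.49,pha_ipl-07
Pha1b i.pl.,0.01,nmol/site,12.31,pha_ipl-08
Pha1b i.pl.,0.03,nmol/site,18.9,pha_ipl-09
Pha1b i.pl.,0.03,nmol/site,31.71,pha_ipl-10
Pha1b i.pl.,0.03,nmol/site,18.69,pha_ipl-11
Pha1b i.pl.,0.03,nmol/site,44.92,pha_ipl-12
Pha1b i.pl.,0.03,nmol/site,7.54,pha_ipl-13
Pha1b i.pl.,0.03,nmol/site,30.51,pha_ipl-14
Pha1b i.pl.,0.03,nmol/site,30.51,pha_ipl-15
Pha1b i.pl.,0.03,nmol/site,-15.59,pha_ipl-16
Pha1b i.pl.,0.1,nmol/site,64.63,pha_ipl-17
Pha1b i.pl.,0.1,nmol/site,26.22,pha_ipl-18
Pha1b i.pl.,0.1,nmol/site,50.61,pha_ipl-19
Pha1b i.pl.,0.1,nmol/site,48.17,pha_ipl-20
Pha1b i.pl.,0.1,nmol/site,8.2,pha_ipl-21
Pha1b i.pl.,0.1,nmol/site,14.1,pha_ipl-22
Pha1b i.pl.,0.1,nmol/site,35.74,pha_ipl-23
Pha1b i.pl.,0.1,nmol/site,37.05,pha_ipl-24
Pha1b i.pl.,0.1,nmol/site,25.84,pha_ipl-25
Pha1b i.pl.,0.1,nmol/site,29.18,pha_ipl-26
Pha1b i.pl.,0.1,nmol/site,38.53,pha_ipl-27
Pha1b i.pl.,0.3,nmol/site,54.27,pha_ipl-28
Pha1b i.pl.,0.3,nmol/site,44.51,pha_ipl-29
Pha1b i.pl.,0.3,nmol/site,43.61,pha_ipl-30
Pha1b i.pl.,0.3,nmol/site,20.0,pha_ipl-31
Pha1b i.pl.,0.3,nmol/site,30.49,pha_ipl-32
Pha1b i.pl.,0.3,nmol/site,45.88,pha_ipl-33
Pha1b i.pl.,0.3,nmol/site,55.23,pha_ipl-34
Pha1b i.pl.,0.3,nmol/site,5.12,pha_ipl-35
Pha1b i.pl.,0.5,nmol/site,67.68,pha_ipl-36
Pha1b i.pl.,0.5,nmol/site,68.29,pha_ipl-37
Pha1b i.pl.,0.5,nmol/site,62.2,pha_ipl-38
Pha1b i.pl.,0.5,nmol/site,62.8,pha_ipl-39
Pha1b i.pl.,0.5,nmol/site,65.85,pha_ipl-40
Pha1b i.pl.,0.5,nmol/site,30.49,pha_ipl-41
Pha1b i.pl.,0.5,nmol/site,35.08,pha_ipl-42
Pha1b i.pl.,0.5,nmol/site,41.64,pha_ipl-43
Pha1b i.pl.,0.5,nmol/site,41.64,pha_ipl-44
Pha1b i.pl.,0.5,nmol/site,41.87,pha_ipl-45
Pha1b i.pl.,0.5,nmol/site,58.57,pha_ipl-46
Pha1b i.pl.,0.5,nmol/site,56.57,pha_ipl-47
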