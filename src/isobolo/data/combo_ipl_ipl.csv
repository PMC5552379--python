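# Dose-effect data: fixed-ratio combination, both drugs intraplantar.
# Dose is the composed pair total (nmol/site); response in %MPE.
regimen,dose,unit,response,subject_id
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,34.0,combo_ipl_ipl-01
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,24.85,combo_ipl_ipl-02
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,3.93,combo_ipl_ipl-03
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,27.5,combo_ipl_ipl-04
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,-19.89,combo_ipl_ipl-05
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,-2.37,combo_ipl_ipl-06
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,32.66,combo_ipl_ipl-07
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,-63.64,combo_ipl_ipl-08
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,25.0,combo_ipl_ipl-09
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,29.09,combo_ipl_ipl-10
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,-20.0,combo_ipl_ipl-11
SB366791 i.pl. + Pha1b i.pl.,0.013,nmol/site,25.68,combo_ipl_ipl-12
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,36.81,combo_ipl_ipl-13
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,43.56,combo_ipl_ipl-14
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,26.38,combo_ipl_ipl-15
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,30.86,combo_ipl_ipl-16
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,29.27,combo_ipl_ipl-17
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,44.01,combo_ipl_ipl-18
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,26.09,combo_ipl_ipl-19
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,39.23,combo_ipl_ipl-20
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,38.14,combo_ipl_ipl-21
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,27.05,combo_ipl_ipl-22
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,20.23,combo_ipl_ipl-23
SB366791 i.pl. + Pha1b i.pl.,0.038,nmol/site,16.82,combo_ipl_ipl-24
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,15.95,combo_ipl_ipl-25
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,46.01,combo_ipl_ipl-26
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,27.61,combo_ipl_ipl-27
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,50.1,combo_ipl_ipl-28
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,44.09,combo_ipl_ipl-29
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,28.09,combo_ipl_ipl-30
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,32.22,combo_ipl_ipl-31
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,46.37,combo_ipl_ipl-32
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,26.09,combo_ipl_ipl-33
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,41.42,combo_ipl_ipl-34
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,37.59,combo_ipl_ipl-35
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,31.82,combo_ipl_ipl-36
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,25.0,combo_ipl_ipl-37
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,16.0,combo_ipl_ipl-38
SB366791 i.pl. + Pha1b i.pl.,0.115,nmol/site,16.82,combo_ipl_ipl-39
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,51.53,combo_ipl_ipl-40
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,52.15,combo_ipl_ipl-41
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,31.9,combo_ipl_ipl-42
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,54.31,combo_ipl_ipl-43
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,51.3,combo_ipl_ipl-44
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,59.12,combo_ipl_ipl-45
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,40.01,combo_ipl_ipl-46
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,33.99,combo_ipl_ipl-47
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,46.9,combo_ipl_ipl-48
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,60.04,combo_ipl_ipl-49
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,74.27,combo_ipl_ipl-50
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,35.91,combo_ipl_ipl-51
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,30.45,combo_ipl_ipl-52
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,36.59,combo_ipl_ipl-53
SB366791 i.pl. + Pha1b i.pl.,0.346,nmol/site,15.45,combo_ipl_ipl-54
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,52.76,combo_ipl_ipl-55
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,60.12,combo_ipl_ipl-56
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,53.99,combo_ipl_ipl-57
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,86.77,combo_ipl_ipl-58
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,49.5,combo_ipl_ipl-59
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,63.93,combo_ipl_ipl-60
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,54.03,combo_ipl_ipl-61
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,45.78,combo_ipl_ipl-62
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,49.9,combo_ipl_ipl-63
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,49.64,combo_ipl_ipl-64
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,65.51,combo_ipl_ipl-65
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,59.49,combo_ipl_ipl-66
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,45.45,combo_ipl_ipl-67
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,45.45,combo_ipl_ipl-68
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,16.14,combo_ipl_ipl-69
SB366791 i.pl. + Pha1b i.pl.,1.038,nmol/site,50.23,combo_ipl_ipl-70
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,54.6,combo_ipl_ipl-71
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,63.8,combo_ipl_ipl-72
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,66.26,combo_ipl_ipl-73
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,69.94,combo_ipl_ipl-74
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,61.52,combo_ipl_ipl-75
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,65.13,combo_ipl_ipl-76
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,61.1,combo_ipl_ipl-77
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,58.74,combo_ipl_ipl-78
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,68.17,combo_ipl_ipl-79
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,67.7,combo_ipl_ipl-80
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,68.25,combo_ipl_ipl-81
SB366791 i.pl. + Pha1b i.pl.,3.114,nmol/site,72.08,combo_ipl_ipl-82
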