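# Dose-effect data: Pha1b intrathecal, capsaicin-induced nociception.
# Doses in nmol/site; response in %MPE; one row per animal.
# Correction: the 13th source row prints dose 0.0003 with log -2.52;
# the dose is stored as 0.003, consistent with the log value and with
# the 0.003 block the row opens.
regimen,dose,unit,response,subject_id
Pha1b i.t.,0.0003,nmol/site,39.54,pha_it-01
Pha1b i.t.,0.0003,nmol/site,-25.58,pha_it-02
Pha1b i.t.,0.0003,nmol/site,31.4,pha_it-03
Pha1b i.t.,0.0003,nmol/site,-4.65,pha_it-04
Pha1b i.t.,0.0003,nmol/site,41.29,pha_it-05
Pha1b i.t.,0.0003,nmol/site,13.11,pha_it-06
Pha1b i.t.,0.0003,nmol/site,4.5,pha_it-07
Pha1b i.t.,0.0003,nmol/site,-0.98,pha_it-08
Pha1b i.t.,0.0003,nmol/site,13.82,pha_it-09
Pha1b i.t.,0.0003,nmol/site,12.88,pha_it-10
Pha1b i.t.,0.0003,nmol/site,-1.17,pha_it-11
Pha1b i.t.,0.0003,nmol/site,20.38,pha_it-12
Pha1b i.t.,0.003,nmol/site,50.0,pha_it-13
Pha1b i.t.,0.003,nmol/site,24.63,pha_it-14
Pha1b i.t.,0.003,nmol/site,39.55,pha_it-15
Pha1b i.t.,0.003,nmol/site,34.18,pha_it-16
Pha1b i.t.,0.003,nmol/site,65.4,pha_it-17
Pha1b i.t.,0.003,nmol/site,20.37,pha_it-18
Pha1b i.t.,0.003,nmol/site,24.07,pha_it-19
Pha1b i.t.,0.003,nmol/site,17.44,pha_it-20
Pha1b i.t.,0.003,nmol/site,23.26,pha_it-21
Pha1b i.t.,0.003,nmol/site,20.93,pha_it-22
Pha1b i.t.,0.003,nmol/site,27.2,pha_it-23
Pha1b i.t.,0.003,nmol/site,63.47,pha_it-24
Pha1b i.t.,0.003,nmol/site,42.86,pha_it-25
Pha1b i.t.,0.003,nmol/site,37.24,pha_it-26
Pha1b i.t.,0.01,nmol/site,19.84,pha_it-27
Pha1b i.t.,0.01,nmol/site,-30.95,pha_it-28
Pha1b i.t.,0.01,nmol/site,47.76,pha_it-29
Pha1b i.t.,0.01,nmol/site,50.0,pha_it-30
Pha1b i.t.,0.01,nmol/site,96.27,pha_it-31
Pha1b i.t.,0.01,nmol/site,40.08,pha_it-32
Pha1b i.t.,0.01,nmol/site,33.33,pha_it-33
Pha1b i.t.,0.01,nmol/site,26.58,pha_it-34
Pha1b i.t.,0.01,nmol/site,26.19,pha_it-35
Pha1b i.t.,0.01,nmol/site,41.67,pha_it-36
Pha1b i.t.,0.01,nmol/site,37.96,pha_it-37
Pha1b i.t.,0.01,nmol/site,35.19,pha_it-38
Pha1b i.t.,0.01,nmol/site,43.52,pha_it-39
Pha1b i.t.,0.01,nmol/site,43.52,pha_it-40
Pha1b i.t.,0.01,nmol/site,45.37,pha_it-41
Pha1b i.t.,0.01,nmol/site,50.0,pha_it-42
Pha1b i.t.,0.1,nmol/site,50.0,pha_it-43
Pha1b i.t.,0.1,nmol/site,36.51,pha_it-44
Pha1b i.t.,0.1,nmol/site,39.55,pha_it-45
Pha1b i.t.,0.1,nmol/site,69.4,pha_it-46
Pha1b i.t.,0.1,nmol/site,68.66,pha_it-47
Pha1b i.t.,0.1,nmol/site,29.11,pha_it-48
Pha1b i.t.,0.1,nmol/site,40.93,pha_it-49
Pha1b i.t.,0.1,nmol/site,28.27,pha_it-50
Pha1b i.t.,0.1,nmol/site,33.33,pha_it-51
Pha1b i.t.,0.1,nmol/site,58.33,pha_it-52
Pha1b i.t.,0.1,nmol/site,42.59,pha_it-53
Pha1b i.t.,0.1,nmol/site,66.67,pha_it-54
Pha1b i.t.,0.1,nmol/site,55.56,pha_it-55
Pha1b i.t.,0.1,nmol/site,59.26,pha_it-56
Pha1b i.t.,0.1,nmol/site,69.44,pha_it-57
Pha1b i.t.,0.3,nmol/site,57.14,pha_it-58
Pha1b i.t.,0.3,nmol/site,-3.97,pha_it-59
Pha1b i.t.,0.3,nmol/site,58.21,pha_it-60
Pha1b i.t.,0.3,nmol/site,71.64,pha_it-61
Pha1b i.t.,0.3,nmol/site,67.91,pha_it-62
Pha1b i.t.,0.3,nmol/site,45.15,pha_it-63
Pha1b i.t.,0.3,nmol/site,51.06,pha_it-64
Pha1b i.t.,0.3,nmol/site,29.96,pha_it-65
Pha1b i.t.,0.3,nmol/site,36.91,pha_it-66
Pha1b i.t.,0.3,nmol/site,60.71,pha_it-67
Pha1b i.t.,0.3,nmol/site,51.85,pha_it-68
Pha1b i.t.,0.3,nmol/site,75.93,pha_it-69
Pha1b i.t.,0.3,nmol/site,55.56,pha_it-70
Pha1b i.t.,0.3,nmol/site,62.96,pha_it-71
Pha1b i.t.,0.3,nmol/site,77.78,pha_it-72
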