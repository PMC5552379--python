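# Dose-effect data: fixed-ratio combination, SB366791 intraplantar
# with Pha1b intrathecal.  Dose is the composed pair total (nmol/site).
regimen,dose,unit,response,subject_id
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,2.0,combo_ipl_it-01
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,-33.77,combo_ipl_it-02
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,32.95,combo_ipl_it-03
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,-34.79,combo_ipl_it-04
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,29.24,combo_ipl_it-05
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,32.19,combo_ipl_it-06
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,49.14,combo_ipl_it-07
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,5.42,combo_ipl_it-08
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,23.73,combo_ipl_it-09
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,37.13,combo_ipl_it-10
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,52.16,combo_ipl_it-11
SB366791 i.pl. + Pha1b i.t.,0.022,nmol/site,34.4,combo_ipl_it-12
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,15.3,combo_ipl_it-13
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,51.72,combo_ipl_it-14
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,50.92,combo_ipl_it-15
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,25.35,combo_ipl_it-16
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,-29.95,combo_ipl_it-17
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,34.4,combo_ipl_it-18
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,39.56,combo_ipl_it-19
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,49.14,combo_ipl_it-20
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,24.75,combo_ipl_it-21
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,32.88,combo_ipl_it-22
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,34.4,combo_ipl_it-23
SB366791 i.pl. + Pha1b i.t.,0.066,nmol/site,26.88,combo_ipl_it-24
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,27.18,combo_ipl_it-25
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,5.01,combo_ipl_it-26
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,54.88,combo_ipl_it-27
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,14.98,combo_ipl_it-28
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,-2.3,combo_ipl_it-29
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,50.23,combo_ipl_it-30
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,52.09,combo_ipl_it-31
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,46.93,combo_ipl_it-32
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,68.3,combo_ipl_it-33
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,31.86,combo_ipl_it-34
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,40.0,combo_ipl_it-35
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,59.32,combo_ipl_it-36
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,35.08,combo_ipl_it-37
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,34.0,combo_ipl_it-38
SB366791 i.pl. + Pha1b i.t.,0.2,nmol/site,55.58,combo_ipl_it-39
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,62.01,combo_ipl_it-40
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,37.47,combo_ipl_it-41
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,35.88,combo_ipl_it-42
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,70.28,combo_ipl_it-43
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,54.38,combo_ipl_it-44
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,53.69,combo_ipl_it-45
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,54.3,combo_ipl_it-46
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,53.56,combo_ipl_it-47
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,65.36,combo_ipl_it-48
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,41.02,combo_ipl_it-49
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,36.95,combo_ipl_it-50
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,59.32,combo_ipl_it-51
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,52.16,combo_ipl_it-52
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,41.23,combo_ipl_it-53
SB366791 i.pl. + Pha1b i.t.,0.6,nmol/site,56.95,combo_ipl_it-54
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,81.0,combo_ipl_it-55
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,71.5,combo_ipl_it-56
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,52.51,combo_ipl_it-57
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,71.66,combo_ipl_it-58
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,57.14,combo_ipl_it-59
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,59.22,combo_ipl_it-60
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,74.2,combo_ipl_it-61
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,54.3,combo_ipl_it-62
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,67.57,combo_ipl_it-63
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,52.2,combo_ipl_it-64
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,43.05,combo_ipl_it-65
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,63.39,combo_ipl_it-66
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,44.65,combo_ipl_it-67
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,48.75,combo_ipl_it-68
SB366791 i.pl. + Pha1b i.t.,1.8,nmol/site,63.78,combo_ipl_it-69
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,77.88,combo_ipl_it-70
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,57.83,combo_ipl_it-71
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,68.89,combo_ipl_it-72
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,76.41,combo_ipl_it-73
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,56.51,combo_ipl_it-74
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,69.78,combo_ipl_it-75
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,65.42,combo_ipl_it-76
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,52.2,combo_ipl_it-77
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,67.46,combo_ipl_it-78
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,57.63,combo_ipl_it-79
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,61.05,combo_ipl_it-80
SB366791 i.pl. + Pha1b i.t.,5.4,nmol/site,65.15,combo_ipl_it-81
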