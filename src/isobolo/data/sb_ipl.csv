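# Dose-effect data: SB366791 intraplantar, capsaicin-induced nociception.
# Doses in nmol/site; response in %MPE; one row per animal.
# Row 12 of the source prints x_i = +1.00 for dose 0.10; the log column
# is never trusted here - x is always recomputed as log10(dose).
regimen,dose,unit,response,subject_id
SB366791 i.pl.,0.1,nmol/site,8.86,sb_ipl-01
SB366791 i.pl.,0.1,nmol/site,-14.77,sb_ipl-02
SB366791 i.pl.,0.1,nmol/site,-41.77,sb_ipl-03
SB366791 i.pl.,0.1,nmol/site,38.29,sb_ipl-04
SB366791 i.pl.,0.1,nmol/site,37.43,sb_ipl-05
SB366791 i.pl.,0.1,nmol/site,-22.57,sb_ipl-06
SB366791 i.pl.,0.1,nmol/site,-23.58,sb_ipl-07
SB366791 i.pl.,0.1,nmol/site,0.81,sb_ipl-08
SB366791 i.pl.,0.1,nmol/site,-10.76,sb_ipl-09
SB366791 i.pl.,0.1,nmol/site,-0.63,sb_ipl-10
SB366791 i.pl.,0.1,nmol/site,-13.83,sb_ipl-11
SB366791 i.pl.,0.1,nmol/site,64.31,sb_ipl-12
SB366791 i.pl.,0.1,nmol/site,48.42,sb_ipl-13
SB366791 i.pl.,0.1,nmol/site,18.18,sb_ipl-14
SB366791 i.pl.,0.4,nmol/site,-13.08,sb_ipl-15
SB366791 i.pl.,0.4,nmol/site,-23.21,sb_ipl-16
SB366791 i.pl.,0.4,nmol/site,4.64,sb_ipl-17
SB366791 i.pl.,0.4,nmol/site,9.14,sb_ipl-18
SB366791 i.pl.,0.4,nmol/site,36.57,sb_ipl-19
SB366791 i.pl.,0.4,nmol/site,27.14,sb_ipl-20
SB366791 i.pl.,0.4,nmol/site,45.8,sb_ipl-21
SB366791 i.pl.,0.4,nmol/site,33.33,sb_ipl-22
SB366791 i.pl.,0.4,nmol/site,0.27,sb_ipl-23
SB366791 i.pl.,0.4,nmol/site,12.03,sb_ipl-24
SB366791 i.pl.,0.4,nmol/site,59.49,sb_ipl-25
SB366791 i.pl.,1.0,nmol/site,-25.75,sb_ipl-26
SB366791 i.pl.,1.0,nmol/site,18.16,sb_ipl-27
SB366791 i.pl.,1.0,nmol/site,12.2,sb_ipl-28
SB366791 i.pl.,1.0,nmol/site,-1.9,sb_ipl-29
SB366791 i.pl.,1.0,nmol/site,17.72,sb_ipl-30
SB366791 i.pl.,1.0,nmol/site,25.32,sb_ipl-31
SB366791 i.pl.,1.0,nmol/site,2.53,sb_ipl-32
SB366791 i.pl.,1.0,nmol/site,5.06,sb_ipl-33
SB366791 i.pl.,1.0,nmol/site,-19.61,sb_ipl-34
SB366791 i.pl.,1.0,nmol/site,6.43,sb_ipl-35
SB366791 i.pl.,1.0,nmol/site,-12.06,sb_ipl-36
SB366791 i.pl.,1.0,nmol/site,50.79,sb_ipl-37
SB366791 i.pl.,1.0,nmol/site,29.37,sb_ipl-38
SB366791 i.pl.,1.0,nmol/site,15.08,sb_ipl-39
SB366791 i.pl.,1.0,nmol/site,44.44,sb_ipl-40
SB366791 i.pl.,1.0,nmol/site,31.75,sb_ipl-41
SB366791 i.pl.,2.0,nmol/site,26.58,sb_ipl-42
SB366791 i.pl.,2.0,nmol/site,70.46,sb_ipl-43
SB366791 i.pl.,2.0,nmol/site,53.59,sb_ipl-44
SB366791 i.pl.,2.0,nmol/site,22.86,sb_ipl-45
SB366791 i.pl.,2.0,nmol/site,40.86,sb_ipl-46
SB366791 i.pl.,2.0,nmol/site,13.43,sb_ipl-47
SB366791 i.pl.,2.0,nmol/site,13.28,sb_ipl-48
SB366791 i.pl.,2.0,nmol/site,22.49,sb_ipl-49
SB366791 i.pl.,2.0,nmol/site,52.85,sb_ipl-50
SB366791 i.pl.,2.0,nmol/site,-10.13,sb_ipl-51
SB366791 i.pl.,6.0,nmol/site,30.62,sb_ipl-52
SB366791 i.pl.,6.0,nmol/site,65.31,sb_ipl-53
SB366791 i.pl.,6.0,nmol/site,17.07,sb_ipl-54
SB366791 i.pl.,6.0,nmol/site,84.28,sb_ipl-55
SB366791 i.pl.,6.0,nmol/site,25.95,sb_ipl-56
SB366791 i.pl.,6.0,nmol/site,23.42,sb_ipl-57
SB366791 i.pl.,6.0,nmol/site,18.99,sb_ipl-58
SB366791 i.pl.,6.0,nmol/site,6.33,sb_ipl-59
SB366791 i.pl.,6.0,nmol/site,60.13,sb_ipl-60
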