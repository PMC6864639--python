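# Molar extinction coefficients (cm^-1 / (mol/L)) of the main visible-range
# skin chromophores, compiled (approximate, 10 nm spacing, linearly
# interpolated on load) from the standard tissue-optics compilations of
# hemoglobin and bilirubin absorption.  Oxy-/deoxy-hemoglobin show the Soret
# bands near 415/430 nm, the oxy Q-band doublet at 542/577 nm and the deoxy
# single Q band near 555 nm; bilirubin peaks near 460 nm and is transparent
# beyond ~550 nm.
wavelength_nm,eps_oxy_hb,eps_deoxy_hb,eps_bilirubin
400,266232,223296,28000
410,466840,303956,34000
420,480360,407560,40000
430,246072,528600,46000
440,102580,413280,51000
450,62816,103292,54500
460,44480,41520,55000
470,33209,29640,51000
480,26629,22950,42000
490,23684,20932,30000
500,20932,20862,18000
510,20051,24561,9000
520,24202,30885,4000
530,39956,39036,1500
540,53236,46592,500
550,43016,52276,150
560,32613,53788,50
570,44496,45072,15
580,50104,37020,5
590,14400,28324,0
600,3200,14677,0
610,1506,9443,0
620,942,6509,0
630,610,5149,0
640,442,4345,0
650,368,3750,0
660,319,3227,0
670,294,2795,0
680,277,2407,0
690,276,2051,0
700,290,1794,0
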