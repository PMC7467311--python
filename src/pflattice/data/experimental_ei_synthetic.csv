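# Synthetic stand-in table of microtubule flexural-rigidity measurements.
# Values are representative magnitudes for thermal-fluctuation assays
# (units: 1e-24 N m^2); they are NOT transcribed from any publication and
# exist to exercise the inverse-variance consensus machinery.
study_key,nucleotide_or_treatment,EI_value,EI_sd,method
synthA1993,GDP,26.0,8.0,thermal_fluctuations
synthB1994,GDP,31.0,7.0,thermal_fluctuations
synthC1995,GDP,22.0,6.0,thermal_fluctuations
synthD2004,GDP,27.0,9.0,thermal_fluctuations
synthE1993,Taxol,21.5,5.5,thermal_fluctuations
synthF1995,Taxol,18.0,6.0,thermal_fluctuations
synthG2006,Taxol,24.0,7.5,thermal_fluctuations
synthH1994,GMPCPP,62.0,15.0,thermal_fluctuations
synthI2007,GMPCPP,55.0,12.0,thermal_fluctuations
synthJ2014,GMPCPP,48.0,14.0,thermal_fluctuations
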