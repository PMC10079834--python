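site_year,n2o_flux,n2o_se,ch4_flux,ch4_se,chamber_co2,nee,nee_se,reco,gpp
2017-2018,610.5,68.1,-44.0,2.2,5869.5,-1757,85,6485,8242
2018-2019,901.9,74.5,-31.6,2.5,4135.0,-1989,86,6141,8129
2019-2020,777.1,52.0,-60.6,2.8,5217.3,-2942,101,6513,9455
2020-2021,263.6,5.6,-78.2,8.8,4565.2,-2632,93,6521,9153
all,624.4,27.8,-53.5,2.5,4925.9,-2330,46,6451,8745
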