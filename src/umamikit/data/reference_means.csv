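# Published species-mean concentrations (mg per 100 g dry weight) for six
# farmed bivalve species, used by `umamikit reproduce` and the test suite.
# source column:
#   reported            - mean printed directly in the source tables/text
#   tav_x_threshold     - mean reconstructed as printed taste-activity value
#                         x detection threshold (2-dp TAV, so +-0.005xT)
# sd is left blank where the dispersion was not published.
species,compound,mean,sd,n,source
M. meretrix,GMP,253.83,27.46,10,reported
C. sinensis,GMP,196.48,19.44,10,reported
M. mercenaria,GMP,243.11,25.96,10,reported
R. philippinarum,GMP,203.02,9.93,10,reported
C. sikamea,GMP,265.17,100.1,10,reported
S. constricta,GMP,226.08,22.66,10,reported
M. meretrix,AMP,111.14,46.93,10,reported
C. sinensis,AMP,51.08,9.08,10,reported
M. mercenaria,AMP,131.29,21.75,10,reported
R. philippinarum,AMP,64.26,14.1,10,reported
C. sikamea,AMP,152.49,66.28,10,reported
S. constricta,AMP,31.34,17.04,10,reported
M. meretrix,Glu,434.10,,10,tav_x_threshold
C. sinensis,Glu,496.80,,10,tav_x_threshold
M. mercenaria,Glu,375.60,,10,tav_x_threshold
R. philippinarum,Glu,285.03,,10,reported
C. sikamea,Glu,553.46,,10,reported
S. constricta,Glu,325.51,,10,reported
C. sinensis,Asp,86.00,,10,tav_x_threshold
M. mercenaria,Asp,328.00,,10,tav_x_threshold
C. sikamea,Asp,320.00,,10,tav_x_threshold
M. meretrix,Arg,276.50,,10,tav_x_threshold
C. sinensis,Arg,743.00,,10,tav_x_threshold
M. mercenaria,Arg,236.50,,10,tav_x_threshold
R. philippinarum,Arg,425.50,,10,tav_x_threshold
C. sikamea,Arg,100.00,,10,tav_x_threshold
S. constricta,Arg,634.00,,10,tav_x_threshold
M. meretrix,Ala,96.30,,10,tav_x_threshold
C. sinensis,Ala,78.18,,10,tav_x_threshold
M. mercenaria,Ala,34.26,,10,tav_x_threshold
R. philippinarum,Ala,34.50,,10,tav_x_threshold
C. sikamea,Ala,45.84,,10,tav_x_threshold
S. constricta,Ala,149.34,,10,tav_x_threshold
M. mercenaria,Tau,2434.33,,10,reported
C. sikamea,Tau,2046.00,,10,reported
S. constricta,Tau,322.10,,10,reported
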