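taxon,group,n_isotherms_negative,movement_cooling_km,movement_warming_km,sst_correlation_sign,abundance_mean,abundance_sd
Ditylum brightwellii,DIA,0,-420.56,372.59,+,0.1307,0.0715
Eucampia zodiacus,DIA,3,56.20,-224.64,,0.0550,0.0227
Pseudo-nitzschia complex,DIA,3,-56.41,159.63,,0.9588,0.3779
Pseudo-nitzschia seriata complex,DIA,3,-136.93,83.11,,0.8218,0.2854
Proboscia indica,DIA,2,-66.26,169.63,,0.3438,0.1881
Rhizosolenia hebetata semispina,DIA,3,-61.16,97.59,,0.5862,0.1417
Rhizosolenia imbricata,DIA,3,-21.88,65.82,,0.6377,0.2714
Rhizosolenia styliformis,DIA,3,-137.41,65.72,-,0.7889,0.2702
Skeletonema costatum,DIA,0,11.90,157.61,,0.1933,0.0988
Thalassiosira spp.,DIA,3,-135.22,34.81,+,1.9102,0.3656
Thalassiothrix longissima,DIA,3,-147.47,79.34,,0.5123,0.3841
Thalassionema nitzschioides,DIA,3,-98.02,99.99,,1.3269,0.4794
Ceratium furca,DIN,2,-101.53,238.79,-,1.6862,0.5181
Ceratium fusus,DIN,3,-104.42,103.66,-,2.5022,0.6574
Ceratium lineatum,DIN,1,-165.74,159.97,-,0.6399,0.2109
Ceratium tripos,DIN,2,-76.19,149.08,-,1.0716,0.3533
Ceratium macroceros,DIN,0,-363.97,406.08,,0.6990,0.3994
Ceratium longipes,DIN,0,-1.94,335.85,,0.3721,0.2289
Ceratium minutum,DIN,3,116.35,119.54,,0.0587,0.0324
Ceratium hexacanthum,DIN,0,-74.07,572.92,,0.1088,0.0657
Dinophysis spp.,DIN,3,83.70,-89.27,-,0.2946,0.0898
Noctiluca scintillans,DIN,0,,211.33,+,0.2157,0.1014
Prorocentrum spp.,DIN,0,-353.82,281.29,-,0.1333,0.0654
Protoperidinium spp.,DIN,3,-59.84,87.79,-,0.6387,0.2076
Calanus finmarchicus,CEU,0,46.11,137.62,-,0.5730,0.1721
Calanus helgolandicus,CEU,0,12.36,255.30,+,0.5865,0.1266
Euchaeta acuta,CEU,0,-4.52,181.51,,0.0121,0.0044
Euchaeta hebes,CEU,0,296.32,-100.86,+,0.0311,0.0208
Undeuchaeta plumosa,CEU,0,37.67,57.78,,0.0109,0.0046
Metridia longa,MP,0,-492.04,680.17,,0.0045,0.0046
Metridia lucens,MP,3,-87.49,-38.32,-,0.4789,0.1167
Pleuromamma abdominalis,MP,3,105.99,-70.40,,0.0132,0.0094
Pleuromamma borealis,MP,0,224.49,72.57,+,0.0427,0.0224
Pleuromamma gracilis,MP,3,248.61,-196.79,+,0.0468,0.0203
Pleuromamma robusta,MP,3,-71.12,3.45,-,0.1041,0.0512
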