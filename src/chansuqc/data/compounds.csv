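id,name,class,formula,substituents,parent_id,fingerprint_peak,reference_rt
arginine,arginine,amino_acid,C6H14N4O2,,,,
succinyl_arginine,succinyl arginine,amino_acid,C10H18N4O5,argininyl_diacid(2),,,
glutaryl_arginine,glutaryl arginine,amino_acid,C11H20N4O5,argininyl_diacid(3),,,
adipyl_arginine,adipyl arginine,amino_acid,C12H22N4O5,argininyl_diacid(4),,,
pimeloyl_arginine,pimeloyl arginine,amino_acid,C13H24N4O5,argininyl_diacid(5),,,
suberoyl_arginine,suberoyl arginine,amino_acid,C14H26N4O5,argininyl_diacid(6),,,
azelayl_arginine,azelayl arginine,amino_acid,C15H28N4O5,argininyl_diacid(7),,,
sebacyl_arginine,sebacyl arginine,amino_acid,C16H30N4O5,argininyl_diacid(8),,,
undecanedioyl_arginine,undecanedioyl arginine,amino_acid,C17H32N4O5,argininyl_diacid(9),,P9,25.0
serotonin,serotonin,alkaloid,C10H12N2O,indole_5_OH;alkylamine_side_chain,,P1,5.0
n_methylserotonin,N-methylserotonin,alkaloid,C11H14N2O,indole_5_OH;alkylamine_side_chain,,,
bufotenine,bufotenine,alkaloid,C12H16N2O,indole_5_OH;alkylamine_side_chain,,P3,10.0
bufotenidine,bufotenidine,alkaloid,C13H18N2O,indole_5_OH;alkylamine_side_chain,,P2,7.5
bufalin,bufalin,bufogenin,C24H34O4,3_OH;14_OH,,P30,77.5
gamabufotalin,gamabufotalin,bufogenin,C24H34O5,3_OH;11_OH;14_OH,,P12,32.5
telocinobufagin,telocinobufagin,bufogenin,C24H34O5,3_OH;5_OH;14_OH,,P23,60.0
hydroxybufalin_12b,12-beta-hydroxylbufalin,bufogenin,C24H34O5,3_OH;12_OH;14_OH,,P18,47.5
hydroxybufalin_19,19-hydroxylbufalin,bufogenin,C24H34O5,3_OH;14_OH;19_CH2OH,,P14,37.5
marinobufagin,marinobufagin,bufogenin,C24H32O5,3_OH;5_OH;14_15_epoxy,,P24,62.5
desacetylcinobufagin,desacetylcinobufagin,bufogenin,C24H32O5,3_OH;16_OH;14_15_epoxy,,,
resibufogenin,resibufogenin,bufogenin,C24H32O4,3_OH;14_15_epoxy,,P32,82.5
cinobufagin,cinobufagin,bufogenin,C26H34O6,3_OH;16_OAc;14_15_epoxy,,P31,80.0
epi_cinobufagin,3-epi-cinobufagin,bufogenin,C26H34O6,3_OH;16_OAc;14_15_epoxy,,P33,85.0
cinobufotalin,cinobufotalin,bufogenin,C26H34O7,3_OH;5_OH;16_OAc;14_15_epoxy,,P28,72.5
cinobufaginol,cinobufaginol,bufogenin,C26H34O7,3_OH;16_OAc;14_15_epoxy;19_CH2OH,,P19,50.0
bufotalin,bufotalin,bufogenin,C26H36O6,3_OH;14_OH;16_OAc,,P25,65.0
arenobufagin,arenobufagin,bufogenin,C24H32O6,3_OH;11_OH;14_OH,,P16,42.5
psi_bufarenogin,psi-bufarenogin,bufogenin,C24H32O6,3_OH;12_OH;14_OH,,P10,27.5
hellebrigenin,hellebrigenin,bufogenin,C24H32O6,3_OH;5_OH;14_OH;19_CHO,,P17,45.0
hellebrigenol,hellebrigenol,bufogenin,C24H34O6,3_OH;5_OH;14_OH;19_CH2OH,,P7,20.0
hellebrigenol_ene,"hellebrigenol-9,11-ene",bufogenin,C24H32O5,3_OH;5_OH;14_OH;19_CH2OH,,P8,22.5
bufotalinin_iso,bufotalinin isomer,bufogenin,C24H30O6,3_OH;5_OH;14_15_epoxy;19_CHO,,P11,30.0
resibufagin,resibufagin,bufogenin,C24H30O5,3_OH;14_15_epoxy;19_CHO,,P26,67.5
resibufagin_iso,resibufagin stereoisomer,bufogenin,C24H30O5,3_OH;14_15_epoxy;19_CHO,,P6,17.5
resibufaginol,resibufaginol,bufogenin,C24H32O5,3_OH;14_15_epoxy;19_CH2OH,,P20,52.5
oxo_cinobufotalin,19-oxo-cinobufotalin,bufogenin,C26H32O8,3_OH;5_OH;16_OAc;14_15_epoxy;19_CHO,,P21,55.0
oxo_bufalin,19-oxo-bufalin,bufogenin,C24H32O5,3_OH;14_OH;19_CHO,,P22,57.5
oxo_cinobufagin,19-oxo-cinobufagin,bufogenin,C26H32O7,3_OH;16_OAc;14_15_epoxy;19_CHO,,P27,70.0
hydroxytelocinobufagin_11a,11-alpha-hydroxytelocinobufagin,bufogenin,C24H34O6,3_OH;5_OH;11_OH;14_OH,,P15,40.0
bufalitoxin,bufalitoxin,bufotoxin,C38H58N4O8,argininyl_diacid(6),bufalin,P29,75.0
gamabufotalin_3_oxalate,gamabufotalin-3-oxalate,bufotoxin,C26H34O8,oxalate,gamabufotalin,P13,35.0
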