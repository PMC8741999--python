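# Stand-in deafness gene panel (183 symbols): study genes plus filler symbols
ACTG1
ADGRV1
CDH23
COL4A3
COL4A5
DFNA5
EYA4
LARS2
LOXHD1
MITF
MYO6
MYO7A
TECTA
TMPRSS3
USH2A
WFS1
GJB2
GJB6
SLC26A4
OTOF
POU3F4
POU4F3
STRC
TMC1
PCDH15
USH1C
CLRN1
WHRN
MYO15A
ESPN
TRIOBP
OTOA
MARVELD2
ILDR1
GIPC3
TPRN
PTPRQ
GRXCR1
LHFPL5
SERPINB6
BSND
CABP2
COCH
KCNQ4
DIAPH1
HLPANEL001
HLPANEL002
HLPANEL003
HLPANEL004
HLPANEL005
HLPANEL006
HLPANEL007
HLPANEL008
HLPANEL009
HLPANEL010
HLPANEL011
HLPANEL012
HLPANEL013
HLPANEL014
HLPANEL015
HLPANEL016
HLPANEL017
HLPANEL018
HLPANEL019
HLPANEL020
HLPANEL021
HLPANEL022
HLPANEL023
HLPANEL024
HLPANEL025
HLPANEL026
HLPANEL027
HLPANEL028
HLPANEL029
HLPANEL030
HLPANEL031
HLPANEL032
HLPANEL033
HLPANEL034
HLPANEL035
HLPANEL036
HLPANEL037
HLPANEL038
HLPANEL039
HLPANEL040
HLPANEL041
HLPANEL042
HLPANEL043
HLPANEL044
HLPANEL045
HLPANEL046
HLPANEL047
HLPANEL048
HLPANEL049
HLPANEL050
HLPANEL051
HLPANEL052
HLPANEL053
HLPANEL054
HLPANEL055
HLPANEL056
HLPANEL057
HLPANEL058
HLPANEL059
HLPANEL060
HLPANEL061
HLPANEL062
HLPANEL063
HLPANEL064
HLPANEL065
HLPANEL066
HLPANEL067
HLPANEL068
HLPANEL069
HLPANEL070
HLPANEL071
HLPANEL072
HLPANEL073
HLPANEL074
HLPANEL075
HLPANEL076
HLPANEL077
HLPANEL078
HLPANEL079
HLPANEL080
HLPANEL081
HLPANEL082
HLPANEL083
HLPANEL084
HLPANEL085
HLPANEL086
HLPANEL087
HLPANEL088
HLPANEL089
HLPANEL090
HLPANEL091
HLPANEL092
HLPANEL093
HLPANEL094
HLPANEL095
HLPANEL096
HLPANEL097
HLPANEL098
HLPANEL099
HLPANEL100
HLPANEL101
HLPANEL102
HLPANEL103
HLPANEL104
HLPANEL105
HLPANEL106
HLPANEL107
HLPANEL108
HLPANEL109
HLPANEL110
HLPANEL111
HLPANEL112
HLPANEL113
HLPANEL114
HLPANEL115
HLPANEL116
HLPANEL117
HLPANEL118
HLPANEL119
HLPANEL120
HLPANEL121
HLPANEL122
HLPANEL123
HLPANEL124
HLPANEL125
HLPANEL126
HLPANEL127
HLPANEL128
HLPANEL129
HLPANEL130
HLPANEL131
HLPANEL132
HLPANEL133
HLPANEL134
HLPANEL135
HLPANEL136
HLPANEL137
HLPANEL138
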