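ESR1
G0001
G0002
G0003
G0004
G0005
G0006
G0007
G0008
G0009
G0010
G0011
G0012
G0013
G0014
G0015
G0016
G0017
G0018
G0019
G0020
G0021
G0022
G0023
G0024
G0025
G0026
G0027
G0028
G0029
G0030
G0031
G0032
G0033
G0034
G0035
G0036
G0037
G0038
G0039
G0040
G0041
G0042
G0043
G0044
BG00000
BG00001
BG00002
BG00003
BG00004
BG00005
BG00006
BG00007
BG00008
BG00009
BG00010
BG00011
BG00012
BG00013
BG00014
BG00015
BG00016
BG00017
BG00018
BG00019
BG00020
BG00021
BG00022
BG00023
BG00024
BG00025
BG00026
BG00027
BG00028
BG00029
BG00030
BG00031
BG00032
BG00033
BG00034
BG00035
BG00036
BG00037
BG00038
BG00039
BG00040
BG00041
BG00042
BG00043
BG00044
BG00045
BG00046
BG00047
BG00048
BG00049
BG00050
BG00051
BG00052
BG00053
BG00054
BG00055
BG00056
BG00057
BG00058
BG00059
BG00060
BG00061
BG00062
BG00063
BG00064
BG00065
BG00066
BG00067
BG00068
BG00069
BG00070
BG00071
BG00072
BG00073
BG00074
BG00075
BG00076
BG00077
BG00078
BG00079
BG00080
BG00081
BG00082
BG00083
BG00084
BG00085
BG00086
BG00087
BG00088
BG00089
BG00090
BG00091
BG00092
BG00093
BG00094
BG00095
BG00096
BG00097
BG00098
BG00099
BG00100
BG00101
BG00102
BG00103
BG00104
BG00105
BG00106
BG00107
BG00108
BG00109
BG00110
BG00111
BG00112
BG00113
BG00114
BG00115
BG00116
BG00117
BG00118
BG00119
BG00120
BG00121
BG00122
BG00123
BG00124
BG00125
BG00126
BG00127
BG00128
BG00129
BG00130
BG00131
BG00132
BG00133
BG00134
BG00135
BG00136
BG00137
BG00138
BG00139
BG00140
BG00141
BG00142
BG00143
BG00144
BG00145
BG00146
BG00147
BG00148
BG00149
BG00150
BG00151
BG00152
BG00153
BG00154
BG00155
BG00156
BG00157
BG00158
BG00159
BG00160
BG00161
BG00162
BG00163
BG00164
BG00165
BG00166
BG00167
BG00168
BG00169
BG00170
BG00171
BG00172
BG00173
BG00174
BG00175
BG00176
BG00177
BG00178
BG00179
BG00180
BG00181
BG00182
BG00183
BG00184
BG00185
BG00186
BG00187
BG00188
BG00189
BG00190
BG00191
BG00192
BG00193
BG00194
BG00195
BG00196
BG00197
BG00198
BG00199
BG00200
BG00201
BG00202
BG00203
BG00204
BG00205
BG00206
BG00207
BG00208
BG00209
BG00210
BG00211
BG00212
BG00213
BG00214
BG00215
BG00216
BG00217
BG00218
BG00219
BG00220
BG00221
BG00222
BG00223
BG00224
BG00225
BG00226
BG00227
BG00228
BG00229
BG00230
BG00231
BG00232
BG00233
BG00234
BG00235
BG00236
BG00237
BG00238
BG00239
BG00240
BG00241
BG00242
BG00243
BG00244
BG00245
BG00246
BG00247
BG00248
BG00249
BG00250
BG00251
BG00252
BG00253
BG00254
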