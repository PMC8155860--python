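mir0002	targets	gene000024
mir0002	targets	gene000078
mir0002	targets	gene000094
mir0002	targets	gene000095
mir0002	targets	gene000098
mir0002	targets	gene000099
mir0002	targets	gene000103
mir0007	targets	gene000049
mir0007	targets	gene000069
mir0007	targets	gene000078
mir0010	targets	gene000044
mir0010	targets	gene000049
mir0010	targets	gene000054
mir0010	targets	gene000075
mir0010	targets	gene000095
mir0010	targets	gene000099
mir0010	targets	gene000102
mir0014	targets	gene000017
mir0014	targets	gene000040
mir0014	targets	gene000048
mir0014	targets	gene000077
mir0014	targets	gene000100
mir0015	targets	gene000040
mir0015	targets	gene000053
mir0015	targets	gene000088
mir0015	targets	gene000091
mir0015	targets	gene000100
mir0015	targets	gene000104
mir0015	targets	gene000108
mir0016	targets	gene000026
mir0016	targets	gene000038
mir0016	targets	gene000048
mir0016	targets	gene000052
mir0016	targets	gene000059
mir0016	targets	gene000091
mir0016	targets	gene000108
mir0016	targets	gene000115
mir0020	targets	gene000046
mir0020	targets	gene000049
mir0020	targets	gene000075
mir0020	targets	gene000078
mir0020	targets	gene000111
mir0021	targets	gene000004
mir0021	targets	gene000029
mir0021	targets	gene000053
mir0021	targets	gene000088
mir0022	targets	gene000046
mir0022	targets	gene000049
mir0022	targets	gene000078
mir0022	targets	gene000098
mir0022	targets	gene000102
mir0023	targets	gene000054
mir0023	targets	gene000062
mir0023	targets	gene000066
mir0023	targets	gene000067
mir0023	targets	gene000103
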