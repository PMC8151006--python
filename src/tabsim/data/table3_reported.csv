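country,step,deaths,mi,stroke,copd,cancer,life_years,costs_i_dollars
AR,status_quo,1378,2183,791,1979,637,33127,182534000
AR,step1,459,728,264,660,212,11042,60903000
AR,step2,14883,23571,8539,21371,6876,257767,1966285000
BO,status_quo,141,82,155,224,41,3611,23210000
BO,step1,116,67,127,184,33,2971,18883000
BO,step2,2071,1206,2279,3300,599,53185,339496000
BR,status_quo,40063,171265,33873,76322,21729,1375769,5830459000
BR,step1,5569,20707,4095,9228,2627,166336,689054000
CL,status_quo,729,917,853,1658,294,19083,125663000
CL,step1,184,231,215,418,74,4809,31613000
CL,step2,7381,9286,8639,16785,2978,193212,1272435000
CO,status_quo,7797,24605,10898,12729,3012,203141,1045827000
CO,step1,2787,8795,3896,4550,1077,72615,377631000
MX,step1,1705,4403,1072,3600,641,46564,313186000
MX,step2,15343,39626,9645,32403,5767,419075,2781093000
PE,step1,588,357,553,1144,212,14433,60151000
PE,step2,5294,3210,4974,10293,1911,129896,541355000
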