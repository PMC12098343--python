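city,province,y2015,y2016,y2017,y2018,y2019,y2020,average,rank
Hefei,Anhui,0.559,0.820,0.817,0.832,0.725,1.022,0.796,16
Huaibei,Anhui,0.444,0.671,0.612,1.015,0.730,0.719,0.699,19
Bozhou,Anhui,1.094,1.090,1.060,1.017,1.028,0.727,1.003,4
Suzhou (Anhui),Anhui,0.742,0.737,0.874,1.026,1.035,1.009,0.904,9
Bengbu,Anhui,0.420,0.553,0.518,0.654,1.008,0.727,0.647,21
Fuyang,Anhui,0.427,0.608,0.550,0.497,0.623,0.695,0.567,29
Huainan,Anhui,0.428,0.468,0.485,0.586,0.595,0.505,0.511,36
Chuzhou,Anhui,0.517,0.658,0.591,0.760,0.718,0.578,0.637,22
Lu'an,Anhui,0.394,1.008,1.009,1.045,1.038,1.032,0.921,8
Maanshan,Anhui,0.409,1.022,0.865,1.011,1.006,1.047,0.893,10
Wuhu,Anhui,0.414,0.529,0.500,0.587,0.770,0.598,0.566,31
Xuancheng,Anhui,0.359,0.607,0.501,0.599,0.691,0.683,0.573,28
Tongling,Anhui,1.242,1.095,1.114,1.063,1.085,1.058,1.109,2
Chizhou,Anhui,0.276,0.410,0.339,0.458,0.435,0.440,0.393,40
Anqing,Anhui,0.370,0.610,1.020,0.695,0.788,0.653,0.689,20
Huangshan,Anhui,0.226,0.306,0.303,0.376,0.377,0.462,0.342,41
Nanjing,Jiangsu,0.669,0.819,0.785,0.760,0.819,0.757,0.768,17
Wuxi,Jiangsu,0.579,0.657,0.607,0.602,0.629,0.669,0.624,24
Xuzhou,Jiangsu,0.527,0.515,0.521,0.507,0.538,0.539,0.525,34
Changzhou,Jiangsu,0.689,0.965,0.752,0.827,0.870,0.919,0.837,14
Suzhou (Jiangsu),Jiangsu,1.007,1.043,1.015,1.022,1.012,1.007,1.018,3
Nantong,Jiangsu,0.510,0.570,0.506,0.530,0.663,0.727,0.584,27
Lianyungang,Jiangsu,0.412,0.423,0.422,0.416,0.445,0.533,0.442,39
Huai'an,Jiangsu,0.535,0.523,0.518,0.555,0.527,0.681,0.557,32
Yancheng,Jiangsu,0.471,0.656,0.507,0.575,0.599,0.591,0.566,30
Yangzhou,Jiangsu,0.556,0.847,0.672,0.881,1.008,1.040,0.834,15
Zhenjiang,Jiangsu,0.655,1.010,1.005,1.069,1.060,1.020,0.970,6
Taizhou (Jiangsu),Jiangsu,0.480,0.561,0.501,0.570,0.530,0.659,0.550,33
Suqian,Jiangsu,0.444,0.485,0.483,0.529,0.527,0.658,0.521,35
Hangzhou,Zhejiang,0.532,0.614,0.552,0.606,0.613,0.643,0.593,26
Ningbo,Zhejiang,0.661,1.020,0.924,1.015,1.139,1.004,0.961,7
Wenzhou,Zhejiang,1.019,1.022,1.034,1.035,0.871,1.000,0.997,5
Jiaxing,Zhejiang,0.650,1.004,0.818,0.911,0.927,1.008,0.886,12
Huzhou,Zhejiang,0.539,1.009,1.015,0.690,0.763,1.009,0.838,13
Shaoxing,Zhejiang,0.518,0.566,0.533,0.661,0.687,0.645,0.602,25
Jinhua,Zhejiang,0.475,0.483,0.485,0.626,0.706,1.004,0.630,23
Quzhou,Zhejiang,0.598,0.406,0.375,0.409,0.445,0.529,0.460,37
Zhoushan,Zhejiang,0.495,1.017,0.730,1.025,1.010,1.054,0.889,11
Taizhou (Zhejiang),Zhejiang,0.531,0.668,0.643,0.808,0.913,1.012,0.762,18
Lishui,Zhejiang,0.317,0.376,0.379,0.485,0.529,0.618,0.451,38
Shanghai,Shanghai,1.277,1.274,1.271,1.220,1.237,1.218,1.249,1
All,All,0.572,0.725,0.688,0.745,0.774,0.793,0.716,
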