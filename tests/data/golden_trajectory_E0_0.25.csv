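t_s,S,X,Y,N,Z
0.0,1.0,-0.0,0.0,0.0,0.0
500.0,0.03688316740124001,0.5635667339691202,0.3825127926899242,0.01703730593971564,0.0
1000.0,0.0013603680375478939,0.28699620155525896,0.6414427015588715,0.07020072884832163,0.0
1500.0,5.017468205617528e-05,0.13633406455033995,0.7241342110232436,0.13948154974436033,0.0
2000.0,1.8506011975819082e-06,0.0644279288745094,0.7232742809622215,0.2122959395620715,0.0
2500.0,6.82560337633487e-08,0.030434641599968087,0.6865961894303656,0.28296910071363257,0.0
3000.0,2.517498719438278e-09,0.014376345203315228,0.6364449829874758,0.34917866929171026,0.0
3500.0,9.285332670144929e-11,0.006790906043483368,0.5830531019949838,0.41015599186867957,0.0
4000.0,3.4247247924915922e-12,0.0032077969300774076,0.5309569584372411,0.46583524462925674,0.0
4500.0,1.2631469782464424e-13,0.0015152559796839358,0.48203042957039843,0.5164543144497913,0.0
5000.0,4.658886145103398e-15,0.0007157562437146965,0.4369152893819197,0.562368954374361,0.0
5500.0,1.7183447759316682e-16,0.0003380993094489944,0.3956944681779177,0.6039674325126332,0.0
6000.0,6.33779980237337e-18,0.00015970680528863592,0.35820787411058047,0.6416324190841309,0.0
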