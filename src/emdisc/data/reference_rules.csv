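# published best-of-run farm-selection rules for the Long House Valley scenario
# (canonicalized rule strings; best fitness = RMSE in households)
run,rule,fitness
0,argmax[S_All](F_Mig),753.430820
1,argmax[S_All](-F_Dist - F_Dry + 2*F_Mig),755.270812
2,argmax[S_All](F_Yield + F_HAgri),709.502643
3,argmax[S_All](-F_HAgri + F_Mig),738.949931
4,argmax[S_All](F_Mig),730.475188
5,argmax[S_All](F_Dist),752.519767
6,argmax[S_All](F_Dist),728.293210
7,argmax[S_All](F_Yield),714.205153
8,argmax[S_All](F_Dist - F_Dry),734.249957
9,argmax[S_All](4*F_Dist + F_Dry + F_Qual + F_Water + F_Soc + F_HAge),701.208243
10,argmax[S_All](F_Dist + F_Qual - F_Yield + F_Water + F_Soc + F_Mig),720.281195
11,argmax[S_All](F_Mig),723.633194
12,argmax[S_All](F_Dist + F_Qual + 2*F_Yield + F_Soc + F_HAgri + 2*F_Mig),687.122260
13,argmax[S_All](F_Dist + F_Soc),732.189183
14,argmax[S_All](F_Qual),728.772255
15,argmax[S_All](F_Qual),706.282521
16,argmax[S_All](F_Dist + 2*F_Qual + F_Yield + F_Soc + 3*F_HAge),715.957401
17,argmax[S_All](F_Mig),715.468378
18,argmax[S_All](-F_Dist + F_Soc - F_HAgri),701.438522
19,argmax[S_All](F_Qual + F_Soc + F_Mig),701.300934
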