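# universal Ising order-parameter distribution, d = 3
# L: 12
# beta_c: 0.22165455
# n_clusters: 200000
# sample_every: 2
# seed: 2014
# columns: x	pdf
-1.992353	0.00090345
-1.959147	0.00045173
-1.925942	0.00210806
-1.892736	0.00286094
-1.859530	0.00782994
-1.826324	0.01400354
-1.793118	0.02273693
-1.759912	0.02921169
-1.726706	0.04170947
-1.693500	0.06730734
-1.660294	0.08100972
-1.627089	0.12874222
-1.593883	0.15298491
-1.560677	0.18581041
-1.527471	0.18821962
-1.494265	0.24754645
-1.461059	0.27404777
-1.427853	0.28534095
-1.394647	0.34587238
-1.361441	0.37869788
-1.328236	0.40248884
-1.295030	0.37192197
-1.261824	0.43456146
-1.228618	0.43968104
-1.195412	0.40309114
-1.162206	0.46362257
-1.129000	0.46633293
-1.095794	0.46211681
-1.062588	0.41287856
-1.029383	0.44193967
-0.996177	0.43757298
-0.962971	0.43305570
-0.929765	0.36860931
-0.896559	0.40866244
-0.863353	0.39420717
-0.830147	0.34511950
-0.796941	0.34782986
-0.763735	0.34316201
-0.730530	0.32991135
-0.697324	0.29271915
-0.664118	0.30039852
-0.630912	0.29889276
-0.597706	0.25206372
-0.564500	0.28157655
-0.531294	0.27193971
-0.498088	0.25748444
-0.464882	0.21878649
-0.431677	0.23023024
-0.398471	0.22932679
-0.365265	0.19514610
-0.332059	0.22751988
-0.298853	0.20809561
-0.265647	0.21441979
-0.232441	0.19394150
-0.199235	0.19198401
-0.166029	0.19348977
-0.132824	0.18264832
-0.099618	0.19785647
-0.066412	0.18204602
-0.033206	0.18565983
0.000000	0.17436666
0.033206	0.18565983
0.066412	0.18204602
0.099618	0.19785647
0.132824	0.18264832
0.166029	0.19348977
0.199235	0.19198401
0.232441	0.19394150
0.265647	0.21441979
0.298853	0.20809561
0.332059	0.22751988
0.365265	0.19514610
0.398471	0.22932679
0.431677	0.23023024
0.464882	0.21878649
0.498088	0.25748444
0.531294	0.27193971
0.564500	0.28157655
0.597706	0.25206372
0.630912	0.29889276
0.664118	0.30039852
0.697324	0.29271915
0.730530	0.32991135
0.763735	0.34316201
0.796941	0.34782986
0.830147	0.34511950
0.863353	0.39420717
0.896559	0.40866244
0.929765	0.36860931
0.962971	0.43305570
0.996177	0.43757298
1.029383	0.44193967
1.062588	0.41287856
1.095794	0.46211681
1.129000	0.46633293
1.162206	0.46362257
1.195412	0.40309114
1.228618	0.43968104
1.261824	0.43456146
1.295030	0.37192197
1.328236	0.40248884
1.361441	0.37869788
1.394647	0.34587238
1.427853	0.28534095
1.461059	0.27404777
1.494265	0.24754645
1.527471	0.18821962
1.560677	0.18581041
1.593883	0.15298491
1.627089	0.12874222
1.660294	0.08100972
1.693500	0.06730734
1.726706	0.04170947
1.759912	0.02921169
1.793118	0.02273693
1.826324	0.01400354
1.859530	0.00782994
1.892736	0.00286094
1.925942	0.00210806
1.959147	0.00045173
1.992353	0.00090345
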