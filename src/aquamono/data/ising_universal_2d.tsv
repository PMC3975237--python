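# universal Ising order-parameter distribution, d = 2
# L: 48
# beta_c: 0.44068679350977147
# n_clusters: 200000
# sample_every: 2
# seed: 2014
# columns: x	pdf
-1.358881	0.00287001
-1.336233	0.01986929
-1.313585	0.07197098
-1.290937	0.19096595
-1.268289	0.34418024
-1.245641	0.59519560
-1.222993	0.83009475
-1.200345	1.04711155
-1.177697	1.17913193
-1.155049	1.24094750
-1.132401	1.30408769
-1.109753	1.29304919
-1.087105	1.21909128
-1.064457	1.16588574
-1.041809	1.00074987
-1.019161	0.99059446
-0.996513	0.88396260
-0.973865	0.77909691
-0.951217	0.69697051
-0.928569	0.59276713
-0.905921	0.56870321
-0.883273	0.52013384
-0.860625	0.44816286
-0.837977	0.41063198
-0.815329	0.34572563
-0.792681	0.34263486
-0.770033	0.31437631
-0.747385	0.28214391
-0.724737	0.24924920
-0.702089	0.21922449
-0.679441	0.21767910
-0.656792	0.19317365
-0.634144	0.17153820
-0.611496	0.15012352
-0.588848	0.16668126
-0.566200	0.14040964
-0.543552	0.13356578
-0.520904	0.11855343
-0.498256	0.10022953
-0.475608	0.10354107
-0.452960	0.10707339
-0.430312	0.09890491
-0.407664	0.08587948
-0.385016	0.07991870
-0.362368	0.08058101
-0.339720	0.07925639
-0.317072	0.07572407
-0.294424	0.07307483
-0.271776	0.06446481
-0.249128	0.08102255
-0.226480	0.06358173
-0.203832	0.06601019
-0.181184	0.06027018
-0.158536	0.05011476
-0.135888	0.05960787
-0.113240	0.06159480
-0.090592	0.05519247
-0.067944	0.05033553
-0.045296	0.05585478
-0.022648	0.05740017
0.000000	0.05210169
0.022648	0.05740017
0.045296	0.05585478
0.067944	0.05033553
0.090592	0.05519247
0.113240	0.06159480
0.135888	0.05960787
0.158536	0.05011476
0.181184	0.06027018
0.203832	0.06601019
0.226480	0.06358173
0.249128	0.08102255
0.271776	0.06446481
0.294424	0.07307483
0.317072	0.07572407
0.339720	0.07925639
0.362368	0.08058101
0.385016	0.07991870
0.407664	0.08587948
0.430312	0.09890491
0.452960	0.10707339
0.475608	0.10354107
0.498256	0.10022953
0.520904	0.11855343
0.543552	0.13356578
0.566200	0.14040964
0.588848	0.16668126
0.611496	0.15012352
0.634144	0.17153820
0.656792	0.19317365
0.679441	0.21767910
0.702089	0.21922449
0.724737	0.24924920
0.747385	0.28214391
0.770033	0.31437631
0.792681	0.34263486
0.815329	0.34572563
0.837977	0.41063198
0.860625	0.44816286
0.883273	0.52013384
0.905921	0.56870321
0.928569	0.59276713
0.951217	0.69697051
0.973865	0.77909691
0.996513	0.88396260
1.019161	0.99059446
1.041809	1.00074987
1.064457	1.16588574
1.087105	1.21909128
1.109753	1.29304919
1.132401	1.30408769
1.155049	1.24094750
1.177697	1.17913193
1.200345	1.04711155
1.222993	0.83009475
1.245641	0.59519560
1.268289	0.34418024
1.290937	0.19096595
1.313585	0.07197098
1.336233	0.01986929
1.358881	0.00287001
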