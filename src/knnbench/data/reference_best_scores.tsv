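metric	experiment	performance	score
fisher	brain	precision	0.442
fisher	brain	recall	0.387
fisher	brain	f1	0.378
fisher	brain	accuracy	0.487
sobolev	brain	precision	0.462
sobolev	brain	recall	0.460
sobolev	brain	f1	0.441
sobolev	brain	accuracy	0.526
clark	brain	precision	0.435
clark	brain	recall	0.414
clark	brain	f1	0.404
clark	brain	accuracy	0.493
bhattacharyya	brain	precision	0.434
bhattacharyya	brain	recall	0.398
bhattacharyya	brain	f1	0.394
bhattacharyya	brain	accuracy	0.492
soergel	brain	precision	0.450
soergel	brain	recall	0.444
soergel	brain	f1	0.428
soergel	brain	accuracy	0.518
hassanat	brain	precision	0.462
hassanat	brain	recall	0.460
hassanat	brain	f1	0.443
hassanat	brain	accuracy	0.529
euclidean	brain	precision	0.461
euclidean	brain	recall	0.455
euclidean	brain	f1	0.432
euclidean	brain	accuracy	0.522
manhattan	brain	precision	0.458
manhattan	brain	recall	0.461
manhattan	brain	f1	0.440
manhattan	brain	accuracy	0.524
chebyshev	brain	precision	0.452
chebyshev	brain	recall	0.455
chebyshev	brain	f1	0.438
chebyshev	brain	accuracy	0.521
hamming	brain	precision	0.445
hamming	brain	recall	0.461
hamming	brain	f1	0.432
hamming	brain	accuracy	0.520
canberra	brain	precision	0.466
canberra	brain	recall	0.457
canberra	brain	f1	0.448
canberra	brain	accuracy	0.527
bray_curtis	brain	precision	0.450
bray_curtis	brain	recall	0.445
bray_curtis	brain	f1	0.428
bray_curtis	brain	accuracy	0.518
fisher	breast	precision	0.896
fisher	breast	recall	0.896
fisher	breast	f1	0.892
fisher	breast	accuracy	0.903
sobolev	breast	precision	0.964
sobolev	breast	recall	0.958
sobolev	breast	f1	0.960
sobolev	breast	accuracy	0.964
clark	breast	precision	0.967
clark	breast	recall	0.972
clark	breast	f1	0.969
clark	breast	accuracy	0.971
bhattacharyya	breast	precision	0.905
bhattacharyya	breast	recall	0.895
bhattacharyya	breast	f1	0.896
bhattacharyya	breast	accuracy	0.907
soergel	breast	precision	0.964
soergel	breast	recall	0.966
soergel	breast	f1	0.964
soergel	breast	accuracy	0.967
hassanat	breast	precision	0.963
hassanat	breast	recall	0.966
hassanat	breast	f1	0.964
hassanat	breast	accuracy	0.967
euclidean	breast	precision	0.966
euclidean	breast	recall	0.962
euclidean	breast	f1	0.963
euclidean	breast	accuracy	0.967
manhattan	breast	precision	0.963
manhattan	breast	recall	0.954
manhattan	breast	f1	0.957
manhattan	breast	accuracy	0.962
chebyshev	breast	precision	0.963
chebyshev	breast	recall	0.961
chebyshev	breast	f1	0.960
chebyshev	breast	accuracy	0.964
hamming	breast	precision	0.950
hamming	breast	recall	0.925
hamming	breast	f1	0.934
hamming	breast	accuracy	0.943
canberra	breast	precision	0.966
canberra	breast	recall	0.969
canberra	breast	f1	0.967
canberra	breast	accuracy	0.970
bray_curtis	breast	precision	0.969
bray_curtis	breast	recall	0.969
bray_curtis	breast	f1	0.968
bray_curtis	breast	accuracy	0.971
fisher	lung	precision	0.611
fisher	lung	recall	0.656
fisher	lung	f1	0.602
fisher	lung	accuracy	0.613
sobolev	lung	precision	0.650
sobolev	lung	recall	0.633
sobolev	lung	f1	0.602
sobolev	lung	accuracy	0.618
clark	lung	precision	0.144
clark	lung	recall	0.356
clark	lung	f1	0.198
clark	lung	accuracy	0.307
bhattacharyya	lung	precision	0.553
bhattacharyya	lung	recall	0.600
bhattacharyya	lung	f1	0.511
bhattacharyya	lung	accuracy	0.545
soergel	lung	precision	0.550
soergel	lung	recall	0.578
soergel	lung	f1	0.522
soergel	lung	accuracy	0.545
hassanat	lung	precision	0.489
hassanat	lung	recall	0.544
hassanat	lung	f1	0.464
hassanat	lung	accuracy	0.516
euclidean	lung	precision	0.617
euclidean	lung	recall	0.633
euclidean	lung	f1	0.582
euclidean	lung	accuracy	0.590
manhattan	lung	precision	0.618
manhattan	lung	recall	0.611
manhattan	lung	f1	0.582
manhattan	lung	accuracy	0.585
chebyshev	lung	precision	0.268
chebyshev	lung	recall	0.389
chebyshev	lung	f1	0.262
chebyshev	lung	accuracy	0.351
hamming	lung	precision	0.449
hamming	lung	recall	0.500
hamming	lung	f1	0.418
hamming	lung	accuracy	0.459
canberra	lung	precision	0.584
canberra	lung	recall	0.544
canberra	lung	f1	0.503
canberra	lung	accuracy	0.507
bray_curtis	lung	precision	0.550
bray_curtis	lung	recall	0.578
bray_curtis	lung	f1	0.522
bray_curtis	lung	accuracy	0.545
fisher	prostate	precision	0.868
fisher	prostate	recall	0.792
fisher	prostate	f1	0.769
fisher	prostate	accuracy	0.813
sobolev	prostate	precision	0.856
sobolev	prostate	recall	0.832
sobolev	prostate	f1	0.823
sobolev	prostate	accuracy	0.832
clark	prostate	precision	0.892
clark	prostate	recall	0.836
clark	prostate	f1	0.840
clark	prostate	accuracy	0.861
bhattacharyya	prostate	precision	0.864
bhattacharyya	prostate	recall	0.783
bhattacharyya	prostate	f1	0.755
bhattacharyya	prostate	accuracy	0.803
soergel	prostate	precision	0.836
soergel	prostate	recall	0.820
soergel	prostate	f1	0.812
soergel	prostate	accuracy	0.822
hassanat	prostate	precision	0.864
hassanat	prostate	recall	0.835
hassanat	prostate	f1	0.829
hassanat	prostate	accuracy	0.841
euclidean	prostate	precision	0.856
euclidean	prostate	recall	0.845
euclidean	prostate	f1	0.834
euclidean	prostate	accuracy	0.841
manhattan	prostate	precision	0.846
manhattan	prostate	recall	0.828
manhattan	prostate	f1	0.821
manhattan	prostate	accuracy	0.832
chebyshev	prostate	precision	0.864
chebyshev	prostate	recall	0.845
chebyshev	prostate	f1	0.834
chebyshev	prostate	accuracy	0.841
hamming	prostate	precision	0.625
hamming	prostate	recall	0.625
hamming	prostate	f1	0.594
hamming	prostate	accuracy	0.598
canberra	prostate	precision	0.926
canberra	prostate	recall	0.882
canberra	prostate	f1	0.877
canberra	prostate	accuracy	0.892
bray_curtis	prostate	precision	0.836
bray_curtis	prostate	recall	0.820
bray_curtis	prostate	f1	0.812
bray_curtis	prostate	accuracy	0.822
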