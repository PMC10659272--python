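context	probability
A[C>A]A	0.00551471
A[C>A]C	0.00614782
A[C>A]G	0.00668455
A[C>A]T	0.00704318
C[C>A]A	0.00716912
C[C>A]C	0.00704318
C[C>A]G	0.00668455
C[C>A]T	0.00614782
G[C>A]A	0.00551471
G[C>A]C	0.00488159
G[C>A]G	0.00434486
G[C>A]T	0.00398623
T[C>A]A	0.00386029
T[C>A]C	0.00398623
T[C>A]G	0.00434486
T[C>A]T	0.00488159
A[C>G]A	0.00414682
A[C>G]C	0.00417482
A[C>G]G	0.00405700
A[C>G]T	0.00381128
C[C>G]A	0.00347507
C[C>G]C	0.00309956
C[C>G]G	0.00274191
C[C>G]T	0.00245658
G[C>G]A	0.00228701
G[C>G]C	0.00225900
G[C>G]G	0.00237683
G[C>G]T	0.00262255
T[C>G]A	0.00295876
T[C>G]C	0.00333427
T[C>G]G	0.00369191
T[C>G]T	0.00397724
A[C>T]A	0.01698015
A[C>T]C	0.01536034
A[C>T]G	0.01364089
A[C>T]T	0.01208358
C[C>T]A	0.01092549
C[C>T]C	0.01034293
C[C>T]G	0.01042459
C[C>T]T	0.01115804
G[C>T]A	0.01243161
G[C>T]C	0.01405142
G[C>T]G	0.01577087
G[C>T]T	0.01732818
T[C>T]A	0.01848627
T[C>T]C	0.01906883
T[C>T]G	0.01898718
T[C>T]T	0.01825373
A[T>A]A	0.00401212
A[T>A]C	0.00367022
A[T>A]G	0.00353916
A[T>A]T	0.00363889
C[T>A]A	0.00395424
C[T>A]C	0.00443719
C[T>A]G	0.00501422
C[T>A]T	0.00559748
G[T>A]A	0.00609817
G[T>A]C	0.00644008
G[T>A]G	0.00657114
G[T>A]T	0.00647140
T[T>A]A	0.00615606
T[T>A]C	0.00567310
T[T>A]G	0.00509607
T[T>A]T	0.00451281
A[T>C]A	0.02161658
A[T>C]C	0.02379195
A[T>C]G	0.02682289
A[T>C]T	0.03024797
C[T>C]A	0.03354574
C[T>C]C	0.03621414
C[T>C]G	0.03784695
C[T>C]T	0.03819558
G[T>C]A	0.03720695
G[T>C]C	0.03503158
G[T>C]G	0.03200064
G[T>C]T	0.02857556
T[T>C]A	0.02527779
T[T>C]C	0.02260938
T[T>C]G	0.02097658
T[T>C]T	0.02062795
A[T>G]A	0.00489217
A[T>G]C	0.00538484
A[T>G]G	0.00575735
A[T>G]T	0.00595299
C[T>G]A	0.00594199
C[T>G]C	0.00572600
C[T>G]G	0.00533792
C[T>G]T	0.00483683
G[T>G]A	0.00429901
G[T>G]C	0.00380634
G[T>G]G	0.00343383
G[T>G]T	0.00323818
T[T>G]A	0.00324919
T[T>G]C	0.00346517
T[T>G]G	0.00385326
T[T>G]T	0.00435435
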