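context	probability
A[C>A]A	0.00157942
A[C>A]C	0.00179097
A[C>A]G	0.00197031
A[C>A]T	0.00209014
C[C>A]A	0.00213222
C[C>A]C	0.00209014
C[C>A]G	0.00197031
C[C>A]T	0.00179097
G[C>A]A	0.00157942
G[C>A]C	0.00136788
G[C>A]G	0.00118854
G[C>A]T	0.00106870
T[C>A]A	0.00102662
T[C>A]C	0.00106870
T[C>A]G	0.00118854
T[C>A]T	0.00136788
A[C>G]A	0.00150863
A[C>G]C	0.00152008
A[C>G]G	0.00147188
A[C>G]T	0.00137134
C[C>G]A	0.00123378
C[C>G]C	0.00108014
C[C>G]G	0.00093382
C[C>G]T	0.00081707
G[C>G]A	0.00074769
G[C>G]C	0.00073623
G[C>G]G	0.00078444
G[C>G]T	0.00088498
T[C>G]A	0.00102254
T[C>G]C	0.00117617
T[C>G]G	0.00132250
T[C>G]T	0.00143924
A[C>T]A	0.06392196
A[C>T]C	0.05696320
A[C>T]G	0.04957640
A[C>T]T	0.04288615
C[C>T]A	0.03791095
C[C>T]C	0.03540826
C[C>T]G	0.03575907
C[C>T]T	0.03890998
G[C>T]A	0.04438129
G[C>T]C	0.05134005
G[C>T]G	0.05872684
G[C>T]T	0.06541710
T[C>T]A	0.07039230
T[C>T]C	0.07289499
T[C>T]G	0.07254418
T[C>T]T	0.06939327
A[T>A]A	0.00102791
A[T>A]C	0.00092108
A[T>A]G	0.00088014
A[T>A]T	0.00091130
C[T>A]A	0.00100982
C[T>A]C	0.00116072
C[T>A]G	0.00134100
C[T>A]T	0.00152324
G[T>A]A	0.00167967
G[T>A]C	0.00178650
G[T>A]G	0.00182744
G[T>A]T	0.00179628
T[T>A]A	0.00169776
T[T>A]C	0.00154686
T[T>A]G	0.00136658
T[T>A]T	0.00118435
A[T>C]A	0.00218210
A[T>C]C	0.00245468
A[T>C]G	0.00283446
A[T>C]T	0.00326362
C[T>C]A	0.00367683
C[T>C]C	0.00401119
C[T>C]G	0.00421578
C[T>C]T	0.00425946
G[T>C]A	0.00413559
G[T>C]C	0.00386301
G[T>C]G	0.00348323
G[T>C]T	0.00305407
T[T>C]A	0.00264085
T[T>C]C	0.00230650
T[T>C]G	0.00210191
T[T>C]T	0.00205823
A[T>G]A	0.00121310
A[T>G]C	0.00135420
A[T>G]G	0.00146089
A[T>G]T	0.00151692
C[T>G]A	0.00151377
C[T>G]C	0.00145191
C[T>G]G	0.00134076
C[T>G]T	0.00119725
G[T>G]A	0.00104322
G[T>G]C	0.00090212
G[T>G]G	0.00079543
G[T>G]T	0.00073940
T[T>G]A	0.00074255
T[T>G]C	0.00080441
T[T>G]G	0.00091555
T[T>G]T	0.00105907
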