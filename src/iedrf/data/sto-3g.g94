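! STO-3G minimal basis, Gaussian-94 text dialect.
! Elements bundled as test/fixture basis: H, He, C, N, O.
****
H     0
S   3   1.00
      3.42525091             0.15432897
      0.62391373             0.53532814
      0.16885540             0.44463454
****
He     0
S   3   1.00
      6.36242139             0.15432897
      1.15892300             0.53532814
      0.31364979             0.44463454
****
C     0
S   3   1.00
     71.6168370              0.15432897
     13.0450960              0.53532814
      3.5305122              0.44463454
SP   3   1.00
      2.9412494             -0.09996723             0.15591627
      0.6834831              0.39951283             0.60768372
      0.2222899              0.70011547             0.39195739
****
N     0
S   3   1.00
     99.1061690              0.15432897
     18.0523120              0.53532814
      4.8856602              0.44463454
SP   3   1.00
      3.7804559             -0.09996723             0.15591627
      0.8784966              0.39951283             0.60768372
      0.2857144              0.70011547             0.39195739
****
O     0
S   3   1.00
    130.7093200              0.15432897
     23.8088610              0.53532814
      6.4436083              0.44463454
SP   3   1.00
      5.0331513             -0.09996723             0.15591627
      1.1695961              0.39951283             0.60768372
      0.3803890              0.70011547             0.39195739
****
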