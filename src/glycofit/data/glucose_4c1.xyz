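24
beta-D-glucopyranose 4C1 chair (synthetic fixture; atom order C1-C6 O1-O6 H1-H5 H61 H62 HO1-HO4 HO6)
C      1.037081     1.260816    -0.141824
C      1.585067    -0.075526     0.378831
C      0.811749    -1.217962    -0.268199
C     -0.693263    -1.042706    -0.049281
C     -1.135181     0.362136    -0.494553
C     -2.600591     0.633577    -0.130179
O      1.727057     2.305414     0.531046
O      2.980756    -0.220129     0.075410
O      1.226271    -2.478393     0.281830
O     -1.380210    -2.047289    -0.802631
O     -0.346851     1.390796     0.138928
O     -2.753030     0.729748     1.287148
H      1.226889     1.377909    -1.215767
H      1.495739    -0.133069     1.470810
H      1.036999    -1.277208    -1.340553
H     -0.926815    -1.207904     1.009708
H     -1.037494     0.456765    -1.584088
H     -3.269008    -0.146968    -0.504635
H     -2.920796     1.593211    -0.549626
H      1.369697     3.125801     0.149983
H      3.400487     0.591298     0.427194
H      2.204753    -2.449158     0.279326
H     -0.969187    -2.893455    -0.531201
H     -2.070120     1.362296     1.582321
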