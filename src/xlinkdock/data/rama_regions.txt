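# Favorable (favoured + allowed) Ramachandran regions, two-level set
# collapsed to one classification. Vertices are (phi, psi) in degrees;
# wrap-around at +-180 is handled by the classifier.
region alpha_R
-160 -120
-20 -120
-20 45
-160 45
region beta
-180 85
-40 85
-40 180
-180 180
region beta_wrap
-180 -180
-40 -180
-40 -160
-180 -160
region alpha_L
20 -20
100 -20
100 90
20 90
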