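position,A,C,G,T
-10,0.222343,0.339732,0.240781,0.197144
-9,0.231562,0.296094,0.277657,0.194687
-8,0.203906,0.367389,0.234019,0.194686
-7,0.213125,0.358170,0.224800,0.203905
-6,0.187924,0.427008,0.224800,0.160268
-5,0.194687,0.367389,0.261675,0.176249
-4,0.231562,0.468190,0.199599,0.100649
-3,0.447902,0.123392,0.360626,0.068080
-2,0.259219,0.442990,0.153505,0.144286
-1,0.190381,0.452209,0.243237,0.114173
+4,0.224800,0.169487,0.445446,0.160267
+5,0.243237,0.314532,0.231562,0.210669
+6,0.240781,0.307769,0.259219,0.192231
+7,0.231562,0.298551,0.268438,0.201449
+8,0.243237,0.289332,0.268438,0.198993
+9,0.231562,0.298551,0.259219,0.210668
+10,0.243237,0.280113,0.268438,0.208212
+11,0.231562,0.289332,0.261675,0.217431
+12,0.243237,0.280113,0.259219,0.217431
+13,0.240781,0.280113,0.259219,0.219887
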