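sample,nmr_mg_per_ml,hplc_mg_per_ml
1,19.0,17.9
2,15.8,17.2
3,17.7,16.3
4,21.0,17.6
5,n.d.,n.d.
6,n.d.,n.d.
7,n.d.,n.d.
8,n.d.,n.d.
9,n.d.,n.d.
10,13.7,13.9
11,23.5,22.5
12,14.3,17.0
13,24.3,22.9
14,14.1,17.5
15,18.7,17.5
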