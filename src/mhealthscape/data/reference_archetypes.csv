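archetype_id,specificity,leaks,change,loss,value,clusters,apps
1,standard,none,none,none,none,9,786
2,standard,none,low,none,none,58,5603
3,standard,none,high,none,none,21,2074
4,nonstandard,low,low,none,low,7,216
5,nonstandard,low,low,low,low,21,4602
6,medical,low,high,none,low,13,570
7,medical,high,low,none,low,3,60
8,medical,high,low,none,high,4,500
9,medical,high,low,low,low,4,660
10,medical,high,high,none,high,3,240
11,medical,high,high,low,high,7,570
12,medical,high,high,high,high,25,2098
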