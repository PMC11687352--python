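row,col,conc_mg_g,tile_class
0,0,1.5,more-toxic
0,1,0.5,less-toxic
0,2,1.5,more-toxic
0,3,1.5,more-toxic
0,4,0.5,less-toxic
0,5,1.5,more-toxic
0,6,0.5,less-toxic
0,7,1.5,more-toxic
0,8,1.5,more-toxic
0,9,1.5,more-toxic
0,10,0.5,less-toxic
0,11,0.5,less-toxic
1,0,0.5,less-toxic
1,1,1.5,more-toxic
1,2,0.5,less-toxic
1,3,1.5,more-toxic
1,4,0.5,less-toxic
1,5,1.5,more-toxic
1,6,0.5,less-toxic
1,7,0.5,less-toxic
1,8,0.5,less-toxic
1,9,1.5,more-toxic
1,10,0.5,less-toxic
1,11,1.5,more-toxic
2,0,0.5,less-toxic
2,1,0.5,less-toxic
2,2,1.5,more-toxic
2,3,0.5,less-toxic
2,4,1.5,more-toxic
2,5,0.5,less-toxic
2,6,1.5,more-toxic
2,7,0.5,less-toxic
2,8,1.5,more-toxic
2,9,0.5,less-toxic
2,10,1.5,more-toxic
2,11,0.5,less-toxic
3,0,0.5,less-toxic
3,1,1.5,more-toxic
3,2,0.5,less-toxic
3,3,1.5,more-toxic
3,4,0.5,less-toxic
3,5,1.5,more-toxic
3,6,1.5,more-toxic
3,7,0.5,less-toxic
3,8,0.5,less-toxic
3,9,1.5,more-toxic
3,10,0.5,less-toxic
3,11,1.5,more-toxic
4,0,0.5,less-toxic
4,1,1.5,more-toxic
4,2,0.5,less-toxic
4,3,1.5,more-toxic
4,4,1.5,more-toxic
4,5,1.5,more-toxic
4,6,0.5,less-toxic
4,7,1.5,more-toxic
4,8,1.5,more-toxic
4,9,0.5,less-toxic
4,10,1.5,more-toxic
4,11,0.5,less-toxic
5,0,0.5,less-toxic
5,1,1.5,more-toxic
5,2,1.5,more-toxic
5,3,0.5,less-toxic
5,4,1.5,more-toxic
5,5,0.5,less-toxic
5,6,1.5,more-toxic
5,7,0.5,less-toxic
5,8,0.5,less-toxic
5,9,1.5,more-toxic
5,10,0.5,less-toxic
5,11,1.5,more-toxic
6,0,1.5,more-toxic
6,1,0.5,less-toxic
6,2,0.5,less-toxic
6,3,1.5,more-toxic
6,4,0.5,less-toxic
6,5,1.5,more-toxic
6,6,0.5,less-toxic
6,7,1.5,more-toxic
6,8,1.5,more-toxic
6,9,0.5,less-toxic
6,10,1.5,more-toxic
6,11,0.5,less-toxic
7,0,0.5,less-toxic
7,1,1.5,more-toxic
7,2,1.5,more-toxic
7,3,0.5,less-toxic
7,4,0.5,less-toxic
7,5,1.5,more-toxic
7,6,0.5,less-toxic
7,7,1.5,more-toxic
7,8,0.5,less-toxic
7,9,1.5,more-toxic
7,10,0.5,less-toxic
7,11,1.5,more-toxic
8,0,0.5,less-toxic
8,1,0.5,less-toxic
8,2,0.5,less-toxic
8,3,1.5,more-toxic
8,4,1.5,more-toxic
8,5,0.5,less-toxic
8,6,0.5,less-toxic
8,7,1.5,more-toxic
8,8,1.5,more-toxic
8,9,1.5,more-toxic
8,10,1.5,more-toxic
8,11,0.5,less-toxic
9,0,1.5,more-toxic
9,1,0.5,less-toxic
9,2,1.5,more-toxic
9,3,0.5,less-toxic
9,4,1.5,more-toxic
9,5,0.5,less-toxic
9,6,1.5,more-toxic
9,7,0.5,less-toxic
9,8,0.5,less-toxic
9,9,0.5,less-toxic
9,10,1.5,more-toxic
9,11,1.5,more-toxic
10,0,1.5,more-toxic
10,1,1.5,more-toxic
10,2,0.5,less-toxic
10,3,0.5,less-toxic
10,4,1.5,more-toxic
10,5,0.5,less-toxic
10,6,0.5,less-toxic
10,7,1.5,more-toxic
10,8,1.5,more-toxic
10,9,1.5,more-toxic
10,10,0.5,less-toxic
10,11,0.5,less-toxic
11,0,0.5,less-toxic
11,1,0.5,less-toxic
11,2,1.5,more-toxic
11,3,1.5,more-toxic
11,4,0.5,less-toxic
11,5,1.5,more-toxic
11,6,1.5,more-toxic
11,7,0.5,less-toxic
11,8,0.5,less-toxic
11,9,0.5,less-toxic
11,10,1.5,more-toxic
11,11,1.5,more-toxic
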