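month,smu_id,mean_catch_lb
1,1 OH,0
1,1 ON,119
1,2 OH,0
1,2 ON,468
1,3 OH/PA,0
1,3 ON,159
1,4 NY/PA,0
1,4 ON,0
2,1 OH,0
2,1 ON,43
2,2 OH,0
2,2 ON,383
2,3 OH/PA,0
2,3 ON,0
2,4 NY/PA,0
2,4 ON,0
3,1 OH,56
3,1 ON,1452
3,2 OH,12
3,2 ON,1396
3,3 OH/PA,0
3,3 ON,133
3,4 NY/PA,0
3,4 ON,0
4,1 OH,128
4,1 ON,322
4,2 OH,17
4,2 ON,753
4,3 OH/PA,0
4,3 ON,452
4,4 NY/PA,0
4,4 ON,14
5,1 OH,147
5,1 ON,236
5,2 OH,338
5,2 ON,565
5,3 OH/PA,193
5,3 ON,263
5,4 NY/PA,5
5,4 ON,162
6,1 OH,1
6,1 ON,5
6,2 OH,14
6,2 ON,191
6,3 OH/PA,1261
6,3 ON,56
6,4 NY/PA,2
6,4 ON,199
7,1 OH,0
7,1 ON,0
7,2 OH,0
7,2 ON,0
7,3 OH/PA,456
7,3 ON,80
7,4 NY/PA,0
7,4 ON,4
8,1 OH,0
8,1 ON,0
8,2 OH,0
8,2 ON,0
8,3 OH/PA,6
8,3 ON,0
8,4 NY/PA,0
8,4 ON,55
9,1 OH,0
9,1 ON,0
9,2 OH,0
9,2 ON,14
9,3 OH/PA,1
9,3 ON,21
9,4 NY/PA,4
9,4 ON,6
10,1 OH,932
10,1 ON,2189
10,2 OH,0
10,2 ON,460
10,3 OH/PA,6
10,3 ON,160
10,4 NY/PA,0
10,4 ON,6
11,1 OH,31265
11,1 ON,6723
11,2 OH,2
11,2 ON,417
11,3 OH/PA,0
11,3 ON,124
11,4 NY/PA,0
11,4 ON,14
12,1 OH,2970
12,1 ON,5826
12,2 OH,0
12,2 ON,328
12,3 OH/PA,0
12,3 ON,81
12,4 NY/PA,0
12,4 ON,14
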