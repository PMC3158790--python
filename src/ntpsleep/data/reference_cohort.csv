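subject,nrem,ta,r2
1,1,5,66.1
1,2,4,74.0
1,3,6,37.9
1,4,7,53.8
2,1,4,62.2
2,2,5,35.4
2,3,7,39.6
2,4,7,37.8
3,1,5,64.2
3,2,7,40.6
3,3,5,45.1
3,4,8,46.6
4,1,4,84.8
4,2,8,33.7
4,3,4,60.7
4,4,10,53.8
5,1,3,81.2
5,2,7,67.0
5,3,8,64.4
5,4,6,34.5
6,1,7,72.3
6,2,4,75.7
6,3,4,33.3
6,4,5,58.6
7,1,6,65.7
7,2,7,43.9
7,3,5,75.7
7,4,6,37.7
8,1,6,67.4
8,2,5,61.5
8,3,8,30.9
8,4,7,43.1
9,1,5,65.0
9,2,7,63.7
9,3,9,62.0
9,4,8,40.7
10,1,2,76.0
10,2,6,47.9
10,3,5,65.2
10,4,7,19.0
11,1,7,63.5
11,2,5,75.5
11,3,10,49.7
11,4,7,49.1
12,1,6,61.5
12,2,8,42.7
12,3,7,32.9
12,4,8,41.8
13,1,5,56.5
13,2,7,56.3
13,3,6,52.9
13,4,8,51.9
14,1,7,58.5
14,2,6,66.2
14,3,6,39.5
14,4,6,35.4
15,1,7,57.4
15,2,7,57.8
15,3,9,71.4
15,4,7,41.8
16,1,4,77.5
16,2,8,57.9
16,3,7,50.6
16,4,7,63.1
17,1,5,74.8
17,2,7,61.1
17,3,6,43.3
17,4,7,56.2
18,1,4,73.2
18,2,9,51.9
18,3,9,38.1
18,4,7,60.9
19,1,3,70.5
19,2,6,54.9
19,3,6,55.2
19,4,3,28.7
20,1,5,82.0
20,2,8,45.8
20,3,7,55.7
20,4,5,26.8
21,1,6,63.3
21,2,5,66.3
21,3,7,26.6
21,4,8,53.0
22,1,8,73.0
22,2,7,46.9
22,3,6,57.4
22,4,7,37.0
23,1,7,66.1
23,2,7,63.3
23,3,7,47.7
23,4,7,39.1
24,1,4,70.7
24,2,6,45.5
24,3,8,65.1
24,4,6,28.9
25,1,5,74.9
25,2,8,48.4
25,3,6,61.4
25,4,10,40.2
26,1,6,71.2
26,2,7,55.1
26,3,7,58.8
26,4,7,33.5
27,1,5,83.3
27,2,9,59.5
27,3,7,53.6
27,4,7,36.0
28,1,5,58.7
28,2,7,48.0
28,3,8,47.1
28,4,9,43.7
29,1,5,66.9
29,2,8,65.8
29,3,7,65.2
29,4,8,47.3
30,1,5,63.7
30,2,7,53.9
30,3,8,43.8
30,4,8,34.3
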