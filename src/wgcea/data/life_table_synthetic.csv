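age,residual_le
0,86
1,85
2,84
3,83
4,82
5,81
6,80
7,79
8,78
9,77
10,76
11,75
12,74
13,73
14,72
15,71
16,70
17,69
18,68
19,67
20,66
21,65
22,64
23,63
24,62
25,61
26,60
27,59
28,58
29,57
30,56
31,55
32,54
33,53
34,52
35,51
36,50
37,49
38,48
39,47
40,46
41,45
42,44
43,43
44,42
45,41
46,40
47,39
48,38
49,37
50,36
51,35
52,34
53,33
54,32
55,31
56,30
57,29
58,28
59,27
60,26
61,25
62,24
63,23
64,22
65,21
66,20
67,19
68,18
69,17
70,16
71,15
72,14
73,13
74,12
75,11
76,10
77,9
78,8
79,7
80,6
81,5
82,4
83,3
84,2
85,1
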