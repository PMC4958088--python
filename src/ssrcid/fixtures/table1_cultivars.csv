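# The 66 elite clonal tea (Camellia sinensis) cultivars, transcribed from the
# study's cultivar roster. processing_property: O oolong, G green, B black tea
# (multi-use cultivars carry several letters, '/'-separated).
code,name,origin,processing_property
1,Tie Guan Yin,Fu Jian,O
2,Huang Dan,Fu Jian,O
3,Ben Shan,Fu Jian,O
4,Mao Xie,Fu Jian,O
5,Mei Zhan,Fu Jian,O
6,Feng Yuan Chun,Fu Jian,O
7,Xing Ren Cha,Fu Jian,O
8,Hong Ya Fo Shou,Fu Jian,O
9,Lv Ya Fo Shou,Fu Jian,O
10,Da Ye Wu Long,Fu Jian,O
11,Bai Ya Qi Lan,Fu Jian,O
12,Ba Xian Cha,Fu Jian,O
13,Da Hong Pao,Fu Jian,O
14,Rou Gui,Fu Jian,O
15,Bai Ji Guan,Fu Jian,O
16,Ai Jiao Wu Long,Fu Jian,O
17,Fu Jian Shui Xian,Fu Jian,O
18,Zheng He Da Bai Cha,Fu Jian,G/B
19,Jiu Long Da Bai Cha,Fu Jian,G/B
20,Fu Ding Da Bai Cha,Fu Jian,G/B
21,Fu Ding Da Hao Cha,Fu Jian,G/B
22,Ge Le Cha,Fu Jian,G/B
23,Fu An Da Bai Cha,Fu Jian,G/B
24,Xia Pu Chun Bo Lv,Fu Jian,G/B
25,Xia Pu Yuan Xiao Cha,Fu Jian,G/B
26,Rong Chun Zao,Fu Jian,G/B
27,Fu Yun 6,Fu Jian,G/B
28,Fu Yun 7,Fu Jian,G/B
29,Fu Yun 10,Fu Jian,G/B
30,Fu Yun 20,Fu Jian,G/B
31,Fu Yun 595,Fu Jian,G/B
32,Jin Guan Yin,Fu Jian,O/G/B
33,Huang Guan Yin,Fu Jian,O/G/B
34,Yue Min Xiang,Fu Jian,O/G/B
35,Huang Qi,Fu Jian,O/G/B
36,Jin Mu Dan,Fu Jian,O/G/B
37,Huang Mei Gui,Fu Jian,O/G/B
38,Zi Mu Dan,Fu Jian,O/G/B
39,Zi Mei Gui,Fu Jian,O/G/B
40,Zao Chun Hao,Fu Jian,G/B
41,Chao Yang,Fu Jian,O/G/B
42,Dan Gui,Fu Jian,O/G/B
43,Chuan Lan,Fu Jian,O/G/B
44,Rui Xiang,Fu Jian,O/G/B
45,Jiu Long Pao,Fu Jian,O/G/B
46,Chun Gui,Fu Jian,O/G/B
47,Zao Mei Gui,Fu Jian,G/B
48,Ming Ke 3,Fu Jian,G/B
49,Ming Ke 4,Fu Jian,G/B
50,Chun Tao Xiang,Fu Jian,O/G/B
51,Jin Mei Gui,Fu Jian,O/G/B
52,Zi Guan Yin,Fu Jian,O/G/B
53,Jin Gui Guan Yin,Fu Jian,O/G/B
54,Zhong Cha 108,Zhe Jiang,G/B
55,Wu Niu Zao,Zhe Jiang,G/B
56,Yin Shuang,Zhe Jiang,G/B
57,An Ji Bai Cha,Zhe Jiang,G/B
58,Long Jin 43,Zhe Jiang,G/B
59,Qian Nian Xue,Zhe Jiang,G/B
60,Ping Yang Te Zao,Zhe Jiang,G/B
61,Li Zao Xiang,Zhe Jiang,G/B
62,Si Ji Chun,Tai Wan,O
63,Jin Xuan,Tai Wan,O
64,Bai Mao 2,Guang Dong,O/G/B
65,Feng Huang Dan Cong,Guang Dong,O
66,Xiang Fei Cui,Hu Nan,G/B
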