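# Genotypes of the 66 clonal tea cultivars at the six core SSR markers.
# Each cell is a fragment-size call in bp: two alleles a/b for diploids,
# three a/b/c for the rare triploid calls (cultivars 4 and 18).
code,name,TM442,TM324,TM351,TM569,TM581,TM461
1,Tie Guan Yin,268/292,171/183,244/244,265/269,228/234,192/210
2,Huang Dan,286/286,183/183,244/250,265/273,228/228,192/198
3,Ben Shan,268/280,171/183,244/250,265/269,228/228,198/198
4,Mao Xie,280/280,171/183,244/250,269/273,228/234,192/198/204
5,Mei Zhan,280/280,171/183,244/244,265/269,228/234,192/198
6,Feng Yuan Chun,268/280,171/183,238/244,265/265,228/234,198/198
7,Xing Ren Cha,280/280,177/183,244/244,265/269,234/234,192/198
8,Hong Ya Fo Shou,268/280,171/171,238/244,265/269,228/228,192/204
9,Lv Ya Fo Shou,268/280,171/171,244/244,265/269,222/228,192/198
10,Da Ye Wu Long,268/280,171/171,238/244,269/269,228/228,192/204
11,Bai Ya Qi Lan,280/280,171/177,238/244,269/273,228/234,192/204
12,Ba Xian Cha,280/286,183/183,238/238,265/269,222/228,192/204
13,Da Hong Pao,268/280,177/183,238/262,265/273,228/234,204/204
14,Rou Gui,268/280,171/177,244/244,269/273,228/228,192/204
15,Bai Ji Guan,292/292,183/183,238/244,273/273,222/228,204/204
16,Ai Jiao Wu Long,280/280,171/177,244/244,269/273,228/228,192/198
17,Fu Jian Shui Xian,280/286,171/183,244/256,265/277,228/234,192/198
18,Zheng He Da Bai Cha,286/286,171/177/183,238/250,265/269/273,228/234,198/204/210
19,Jiu Long Da Bai Cha,280/280,183/183,238/244,269/273,228/228,204/210
20,Fu Ding Da Bai Cha,268/280,171/183,244/244,269/273,222/228,204/210
21,Fu Ding Da Hao Cha,280/280,183/183,238/244,269/273,228/228,186/210
22,Ge Le Cha,268/280,171/183,244/244,273/273,222/228,204/210
23,Fu An Da Bai Cha,280/286,183/183,244/256,269/273,222/228,204/204
24,Xia Pu Chun Bo Lv,280/286,183/183,244/250,265/269,228/228,198/210
25,Xia Pu Yuan Xiao Cha,280/286,171/183,238/238,269/273,222/222,204/210
26,Rong Chun Zao,280/286,183/183,238/250,269/273,222/228,192/198
27,Fu Yun 6,280/280,177/183,244/244,265/269,228/240,198/204
28,Fu Yun 7,280/280,162/171,244/250,273/273,222/240,198/204
29,Fu Yun 10,280/280,171/183,244/250,269/273,228/228,204/210
30,Fu Yun 20,280/280,171/171,244/256,269/273,228/240,198/204
31,Fu Yun 595,280/280,177/183,244/250,273/273,222/240,198/210
32,Jin Guan Yin,280/286,171/177,244/250,265/273,228/234,192/192
33,Huang Guan Yin,286/286,177/183,244/250,265/269,222/228,192/204
34,Yue Min Xiang,268/280,171/171,244/244,269/273,228/228,192/204
35,Huang Qi,286/286,183/183,244/244,269/273,228/228,192/192
36,Jin Mu Dan,280/286,171/177,244/244,265/269,222/228,198/198
37,Huang Mei Gui,286/286,177/183,250/250,265/265,222/228,192/204
38,Zi Mu Dan,280/286,171/171,244/256,265/273,228/240,198/204
39,Zi Mei Gui,280/286,171/177,244/244,265/269,228/234,192/192
40,Zao Chun Hao,268/268,171/177,250/250,265/269,222/234,204/210
41,Chao Yang,280/292,171/177,248/250,269/273,222/240,198/198
42,Dan Gui,280/286,171/183,244/244,273/273,228/228,204/204
43,Chuan Lan,286/286,171/183,244/244,269/269,228/228,192/198
44,Rui Xiang,280/286,177/183,244/244,269/273,228/228,192/198
45,Jiu Long Pao,268/280,177/177,244/250,269/269,228/234,198/204
46,Chun Gui,286/286,177/183,244/244,269/273,228/228,192/192
47,Zao Mei Gui,280/286,177/183,244/244,265/269,228/228,192/204
48,Ming Ke 3,280/280,177/183,250/250,265/273,240/240,198/204
49,Ming Ke 4,280/280,171/177,244/250,269/273,222/228,204/204
50,Chun Tao Xiang,286/286,171/183,244/244,265/269,222/228,198/204
51,Jin Mei Gui,280/286,171/171,244/250,265/269,228/234,192/198
52,Zi Guan Yin,286/286,177/183,244/250,269/273,228/234,192/198
53,Jin Gui Guan Yin,280/286,171/171,244/250,265/269,228/234,192/192
54,Zhong Cha 108,280/280,171/183,244/250,265/269,222/234,198/210
55,Wu Niu Zao,268/280,183/183,250/256,265/269,222/222,192/204
56,Yin Shuang,268/286,171/171,244/244,265/273,222/228,204/210
57,An Ji Bai Cha,280/280,177/183,244/256,273/273,228/228,198/204
58,Long Jin 43,280/280,171/177,244/256,273/273,228/228,198/210
59,Qian Nian Xue,286/286,183/183,244/244,265/269,222/234,198/210
60,Ping Yang Te Zao,268/280,183/183,250/256,265/273,222/240,192/198
61,Li Zao Xiang,280/280,177/183,250/250,265/265,222/222,198/210
62,Si Ji Chun,280/280,171/177,244/244,269/273,228/234,192/204
63,Jin Xuan,280/280,171/171,244/250,269/273,228/234,198/204
64,Bai Mao 2,280/292,171/177,244/250,265/273,228/240,204/210
65,Feng Huang Dan Cong,268/286,171/183,244/250,269/269,222/234,198/198
66,Xiang Fei Cui,268/268,177/183,250/256,265/269,234/234,192/210
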