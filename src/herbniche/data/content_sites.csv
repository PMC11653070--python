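site,place,poly_mean,poly_sd,hb_mean,hb_sd,hb_nd
1,"Shouning County, Fujian 1",31.06,2.62,,,True
2,"Shouning County, Fujian 2",32.43,4.06,,,True
3,"Fuan City, Fujian 1",33.12,3.06,,,True
4,"Fuan City, Fujian 2",27.24,1.59,,,True
5,"Zherong County, Fujian 1",27.49,2.56,,,True
6,"Zherong County, Fujian 2",31.31,5.31,,,True
7,"Zherong County, Fujian 3",30.13,1.16,,,True
8,"Zherong County, Fujian 4",28.95,3.74,,,True
9,"Zherong County, Fujian 5",33.43,4.50,,,True
10,"Zherong County, Fujian 6",33.45,3.56,,,True
11,"Zherong County, Fujian 7",28.29,1.97,,,True
12,"Xiapu County, Fujian",33.48,0.47,,,True
13,"Fuding City, Fujian",32.21,2.03,,,True
14,"Dantu District, Jiangsu",33.42,6.45,0.0242,0.0019,False
15,"Jurong City, Jiangsu 1",30.17,2.22,0.0247,0.0026,False
16,"Jurong City, Jiangsu 2",32.44,2.23,0.0298,0.0036,False
17,"Huoshan County, Anhui",27.42,1.95,0.0219,0.0016,False
18,"Shucheng County, Anhui 1",31.14,3.80,0.0261,0.0019,False
19,"Shucheng County, Anhui 2",31.14,0.96,0.0343,0.0024,False
20,"Yu'an District, Anhui",37.04,1.69,0.0222,0.0027,False
21,"Xuanzhou District, Anhui 1",22.61,3.92,0.0204,0.0007,False
22,"Xuanzhou District, Anhui 2",29.63,2.35,0.0188,0.0015,False
23,"Guangde County, Anhui 1",32.63,1.22,0.0124,0.0010,False
24,"Guangde County, Anhui 2",27.65,1.67,0.0065,0.0008,False
25,"Shibin County, Guizhou 1",38.07,1.90,0.0118,0.0017,False
26,"Shibin County, Guizhou 2",35.22,3.06,0.0161,0.0007,False
27,"Shibin County, Guizhou 3",39.42,1.27,0.0231,0.0006,False
28,"Shibin County, Guizhou 4",32.74,1.48,0.0248,0.0026,False
29,"Shibin County, Guizhou 5",25.87,1.74,0.0122,0.0016,False
30,"Shibin County, Guizhou 6",27.99,2.18,0.0140,0.0013,False
31,"Qianxi County, Guizhou",29.75,3.21,0.0258,0.0011,False
32,"Yuping County, Guizhou",30.98,3.51,0.0238,0.0019,False
33,"Qingzhen City, Guizhou",33.21,2.13,0.0111,0.0011,False
34,"Danzhai County, Guizhou",30.64,2.92,0.0267,0.0013,False
35,"Pingtang County, Guizhou",35.28,2.82,0.0171,0.0011,False
36,"Huaxi District, Guizhou",29.09,1.74,0.0188,0.0027,False
37,"Zhenyuan County, Guizhou",28.03,2.10,0.0160,0.0026,False
38,"Fuquan City, Guizhou",29.93,4.01,0.0208,0.0007,False
39,"Yuqing County, Guizhou",21.55,2.35,0.0188,0.0015,False
40,"Huangping County, Guizhou",30.93,4.50,0.0143,0.0017,False
41,"Linshu County, Shandong",32.20,4.34,0.0123,0.0007,False
42,"Luozhuang District, Shandong",32.14,1.53,0.0124,0.0012,False
43,"Yinan County, Shandong",28.68,1.15,0.0147,0.0022,False
44,"Hedong District, Shandong",32.73,2.06,0.0127,0.0016,False
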