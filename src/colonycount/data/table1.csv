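sample_id,gold_rate_mean,gold_rate_sd,gold_count_mean,gold_count_sd,manual_rate_mean,manual_rate_sd,manual_count_mean,manual_count_sd,auto_count,ratio_auto_gold,ratio_manual_gold,segments_per_plate
1,1.14,0.03,174.0,0.0,1.87,0.25,168.0,6.0,174,1.00,0.97,6
2,1.31,0.08,210.0,0.0,1.73,0.17,208.0,3.5,198,0.94,0.99,6
3,1.16,0.21,176.0,3.5,1.88,0.47,188.0,13.9,198,1.13,1.07,6
4,1.52,0.03,234.0,0.0,2.09,0.08,196.0,12.5,210,0.90,0.84,6
5,0.72,0.11,754.7,3.8,1.52,0.27,714.3,22.9,733,0.97,0.95,1
6,1.34,0.19,612.0,19.0,1.65,0.35,578.0,15.0,583,0.95,0.94,1
7,1.38,0.09,579.0,3.5,1.63,0.23,547.7,26.3,566,0.91,0.88,1
8,1.35,0.17,67.3,2.3,1.56,0.63,63.0,5.2,70,1.04,0.94,1
9,1.17,0.19,14.0,0.0,1.91,0.66,14.0,0.0,12,0.86,1.00,1
10,0.82,0.28,316.0,3.5,2.00,0.38,284.0,9.2,318,1.01,0.90,6
11,1.03,0.06,396.0,0.0,2.67,0.51,304.0,12.5,396,1.00,0.77,6
12,0.99,0.07,288.0,0.0,1.52,0.08,276.0,6.0,288,1.00,0.96,6
13,0.80,0.07,418.0,3.3,3.21,0.67,404.0,12.5,414,0.99,0.97,6
14,0.80,0.16,456.0,0.0,2.49,0.33,364.0,9.2,408,0.89,0.80,6
15,0.97,0.10,510.0,0.0,2.57,0.60,442.0,15.1,468,0.92,0.87,6
16,1.03,0.06,81.3,1.1,2.19,0.60,76.7,2.5,80,0.98,0.94,1
17,1.08,0.31,149.7,1.5,1.84,0.46,141.0,8.2,150,1.00,0.94,1
18,0.75,0.11,288.0,0.9,1.83,0.22,272.7,3.8,289,1.00,0.95,1
19,0.87,0.26,246.7,2.0,1.72,0.08,210.3,23.2,235,0.95,0.85,1
20,1.28,0.16,615.3,18.5,1.63,0.29,564.0,7.9,593,0.96,0.92,1
21,1.50,0.28,555.0,10.5,1.40,0.27,459.0,149,547,0.99,0.83,1
22,1.01,0.11,300.0,0.0,1.78,0.24,288.0,6.0,300,1.00,0.96,6
23,1.14,0.30,300.0,0.0,1.35,0.18,276.0,6.0,300,1.00,0.92,6
24,1.20,0.0,230.0,3.5,1.48,0.0,204.0,10.4,210,0.91,0.89,6
25,1.21,0.12,284.0,3.4,2.01,0.05,274.0,3.5,270,0.95,0.96,6
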