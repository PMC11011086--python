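session,sleep_system_hms,sleep_manual_hms,pct_diff_sleep,bouts_system,bouts_manual,pct_diff_bouts
1,12:05:56,09:31:33,1.15,14,15,2.94
2,12:52:49,10:41:49,0.71,7,15,23.53
3,11:42:26,09:59:51,0.39,19,17,5.88
4,11:15:11,10:04:42,0.06,22,20,5.88
5,12:37:12,09:41:49,1.42,12,15,8.82
6,05:26:04,04:58:31,0.13,10,8,5.88
7,11:43:39,09:58:31,0.43,15,15,0.00
8,10:48:40,11:05:58,1.38,23,19,11.76
9,11:56:16,11:15:38,0.59,12,21,26.47
10,12:20:21,10:10:57,0.74,13,16,8.82
11,08:05:47,10:05:20,2.68,18,18,0.00
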