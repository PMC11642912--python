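# WHO world standard population (2000-2025 average world population),
# percentage by 5-year age group.  Version 1; percentages sum to 100.03
# in the published table and are renormalized on load.
age_group,percent
0 to 4,8.86
5 to 9,8.69
10 to 14,8.60
15 to 19,8.47
20 to 24,8.22
25 to 29,7.93
30 to 34,7.61
35 to 39,7.15
40 to 44,6.59
45 to 49,6.04
50 to 54,5.37
55 to 59,4.55
60 to 64,3.72
65 to 69,2.96
70 to 74,2.21
75 to 79,1.52
80 to 84,0.91
85 years or older,0.63
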