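scenario,subject,stress_pct
manual,1,35.37
manual,2,45.71
manual,3,58.8
manual,4,53.91
manual,5,55.74
manual,6,66.25
manual,7,59.76
manual,8,49.59
manual,9,47.37
manual,10,47.9
manual,11,62.98
manual,12,51.26
manual,13,54.2
autonomous,1,38.72
autonomous,2,26.86
autonomous,3,70.29
autonomous,4,39.33
autonomous,5,33.05
autonomous,6,65.81
autonomous,7,15.48
autonomous,8,50.85
autonomous,9,41.35
autonomous,10,12.39
autonomous,11,51.27
autonomous,12,30.21
autonomous,13,22.73
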