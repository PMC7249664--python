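scenario,row_index,row_label,subject,hr_bpm,printed_mean,consistent
manual,1,task 1,1,75.96,86.13,True
manual,1,task 1,2,73.64,86.13,True
manual,1,task 1,3,100.17,86.13,True
manual,1,task 1,4,109.08,86.13,True
manual,1,task 1,5,108.23,86.13,True
manual,1,task 1,6,83.11,86.13,True
manual,1,task 1,7,97.41,86.13,True
manual,1,task 1,8,85.98,86.13,True
manual,1,task 1,9,79.8,86.13,True
manual,1,task 1,10,63.29,86.13,True
manual,1,task 1,11,79.6,86.13,True
manual,1,task 1,12,99.34,86.13,True
manual,1,task 1,13,64.08,86.13,True
manual,2,task 2,1,76.11,86.28,False
manual,2,task 2,2,74.08,86.28,False
manual,2,task 2,3,99.04,86.28,False
manual,2,task 2,4,110.09,86.28,False
manual,2,task 2,5,108.78,86.28,False
manual,2,task 2,6,83.45,86.28,False
manual,2,task 2,7,97.19,86.28,False
manual,2,task 2,8,128.0,86.28,False
manual,2,task 2,9,85.2,86.28,False
manual,2,task 2,10,79.97,86.28,False
manual,2,task 2,11,79.69,86.28,False
manual,2,task 2,12,100.58,86.28,False
manual,2,task 2,13,64.22,86.28,False
manual,3,task 4,1,76.63,86.49,True
manual,3,task 4,2,74.43,86.49,True
manual,3,task 4,3,100.04,86.49,True
manual,3,task 4,4,109.84,86.49,True
manual,3,task 4,5,109.13,86.49,True
manual,3,task 4,6,83.39,86.49,True
manual,3,task 4,7,97.58,86.49,True
manual,3,task 4,8,85.98,86.49,True
manual,3,task 4,9,79.98,86.49,True
manual,3,task 4,10,63.06,86.49,True
manual,3,task 4,11,80.16,86.49,True
manual,3,task 4,12,100.09,86.49,True
manual,3,task 4,13,64.1,86.49,True
manual,4,task 4,1,76.12,86.22,True
manual,4,task 4,2,74.02,86.22,True
manual,4,task 4,3,99.21,86.22,True
manual,4,task 4,4,109.68,86.22,True
manual,4,task 4,5,108.62,86.22,True
manual,4,task 4,6,83.35,86.22,True
manual,4,task 4,7,97.23,86.22,True
manual,4,task 4,8,85.35,86.22,True
manual,4,task 4,9,79.98,86.22,True
manual,4,task 4,10,63.21,86.22,True
manual,4,task 4,11,79.69,86.22,True
manual,4,task 4,12,100.41,86.22,True
manual,4,task 4,13,64.05,86.22,True
manual,5,no tasks,1,74.1,82.74,True
manual,5,no tasks,2,68.98,82.74,True
manual,5,no tasks,3,92.8,82.74,True
manual,5,no tasks,4,97.83,82.74,True
manual,5,no tasks,5,99.92,82.74,True
manual,5,no tasks,6,80.97,82.74,True
manual,5,no tasks,7,87.72,82.74,True
manual,5,no tasks,8,82.38,82.74,True
manual,5,no tasks,9,81.33,82.74,True
manual,5,no tasks,10,63.07,82.74,True
manual,5,no tasks,11,78.4,82.74,True
manual,5,no tasks,12,103.83,82.74,True
manual,5,no tasks,13,64.29,82.74,True
manual,6,whole track,1,74.25,83.09,True
manual,6,whole track,2,69.44,83.09,True
manual,6,whole track,3,93.55,83.09,True
manual,6,whole track,4,99.07,83.09,True
manual,6,whole track,5,100.78,83.09,True
manual,6,whole track,6,81.2,83.09,True
manual,6,whole track,7,88.75,83.09,True
manual,6,whole track,8,82.7,83.09,True
manual,6,whole track,9,81.15,83.09,True
manual,6,whole track,10,63.09,83.09,True
manual,6,whole track,11,78.48,83.09,True
manual,6,whole track,12,103.38,83.09,True
manual,6,whole track,13,64.27,83.09,True
autonomous,1,task 1,1,66.64,75.05,True
autonomous,1,task 1,2,65.89,75.05,True
autonomous,1,task 1,3,81.1,75.05,True
autonomous,1,task 1,4,77.92,75.05,True
autonomous,1,task 1,5,86.81,75.05,True
autonomous,1,task 1,6,78.29,75.05,True
autonomous,1,task 1,7,73.91,75.05,True
autonomous,1,task 1,8,74.99,75.05,True
autonomous,1,task 1,9,81.55,75.05,True
autonomous,1,task 1,10,60.66,75.05,True
autonomous,1,task 1,11,82.03,75.05,True
autonomous,1,task 1,12,81.58,75.05,True
autonomous,1,task 1,13,64.26,75.05,True
autonomous,2,task 2,1,66.47,75.09,True
autonomous,2,task 2,2,65.98,75.09,True
autonomous,2,task 2,3,81.29,75.09,True
autonomous,2,task 2,4,77.75,75.09,True
autonomous,2,task 2,5,86.66,75.09,True
autonomous,2,task 2,6,78.5,75.09,True
autonomous,2,task 2,7,73.84,75.09,True
autonomous,2,task 2,8,74.96,75.09,True
autonomous,2,task 2,9,81.79,75.09,True
autonomous,2,task 2,10,60.8,75.09,True
autonomous,2,task 2,11,81.96,75.09,True
autonomous,2,task 2,12,81.89,75.09,True
autonomous,2,task 2,13,64.32,75.09,True
autonomous,3,task 3,1,66.49,75.1,True
autonomous,3,task 3,2,65.98,75.1,True
autonomous,3,task 3,3,81.29,75.1,True
autonomous,3,task 3,4,77.78,75.1,True
autonomous,3,task 3,5,86.68,75.1,True
autonomous,3,task 3,6,78.48,75.1,True
autonomous,3,task 3,7,73.85,75.1,True
autonomous,3,task 3,8,74.96,75.1,True
autonomous,3,task 3,9,81.76,75.1,True
autonomous,3,task 3,10,60.79,75.1,True
autonomous,3,task 3,11,81.98,75.1,True
autonomous,3,task 3,12,81.87,75.1,True
autonomous,3,task 3,13,64.34,75.1,True
autonomous,4,task 4,1,66.64,75.04,True
autonomous,4,task 4,2,65.89,75.04,True
autonomous,4,task 4,3,81.08,75.04,True
autonomous,4,task 4,4,77.9,75.04,True
autonomous,4,task 4,5,86.81,75.04,True
autonomous,4,task 4,6,78.29,75.04,True
autonomous,4,task 4,7,73.93,75.04,True
autonomous,4,task 4,8,74.99,75.04,True
autonomous,4,task 4,9,81.53,75.04,True
autonomous,4,task 4,10,60.64,75.04,True
autonomous,4,task 4,11,82.02,75.04,True
autonomous,4,task 4,12,81.56,75.04,True
autonomous,4,task 4,13,64.25,75.04,True
autonomous,5,no tasks,1,68.02,75.38,True
autonomous,5,no tasks,2,63.96,75.38,True
autonomous,5,no tasks,3,80.78,75.38,True
autonomous,5,no tasks,4,76.33,75.38,True
autonomous,5,no tasks,5,86.4,75.38,True
autonomous,5,no tasks,6,77.19,75.38,True
autonomous,5,no tasks,7,71.11,75.38,True
autonomous,5,no tasks,8,78.24,75.38,True
autonomous,5,no tasks,9,85.12,75.38,True
autonomous,5,no tasks,10,59.11,75.38,True
autonomous,5,no tasks,11,85.95,75.38,True
autonomous,5,no tasks,12,82.44,75.38,True
autonomous,5,no tasks,13,65.32,75.38,True
autonomous,6,whole track,1,67.86,75.35,True
autonomous,6,whole track,2,64.14,75.35,True
autonomous,6,whole track,3,80.82,75.35,True
autonomous,6,whole track,4,76.49,75.35,True
autonomous,6,whole track,5,86.44,75.35,True
autonomous,6,whole track,6,77.31,75.35,True
autonomous,6,whole track,7,71.41,75.35,True
autonomous,6,whole track,8,77.87,75.35,True
autonomous,6,whole track,9,84.75,75.35,True
autonomous,6,whole track,10,59.29,75.35,True
autonomous,6,whole track,11,85.52,75.35,True
autonomous,6,whole track,12,82.37,75.35,True
autonomous,6,whole track,13,65.22,75.35,True
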