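# synthetic variable-mean periodic inlet signal (stand-in, generated)
t_s,P_mmHg
0.0,66
0.01,68.61613595
0.02,70.99028202
0.03,72.90413595
0.04,74.18445213
0.05,74.72
0.06,74.47245213
0.07,73.48013595
0.08,71.85428202
0.09,69.76813595
0.1,67.44
0.11,65.11186405
0.12,63.02571798
0.13,61.39986405
0.14,60.40754787
0.15,60.16
0.16,60.69554787
0.17,61.97586405
0.18,63.88971798
0.19,66.26386405
0.2,68.88
0.21,71.49613595
0.22,73.87028202
0.23,75.78413595
0.24,77.06445213
0.25,77.6
0.26,77.35245213
0.27,76.36013595
0.28,74.73428202
0.29,72.64813595
0.3,70.32
0.31,67.99186405
0.32,65.90571798
0.33,64.27986405
0.34,63.28754787
0.35,63.04
0.36,63.57554787
0.37,64.85586405
0.38,66.76971798
0.39,69.14386405
0.4,71.76
0.41,74.37613595
0.42,76.75028202
0.43,78.66413595
0.44,79.94445213
0.45,80.48
0.46,80.23245213
0.47,79.24013595
0.48,77.61428202
0.49,75.52813595
0.5,73.2
0.51,70.87186405
0.52,68.78571798
0.53,67.15986405
0.54,66.16754787
0.55,65.92
0.56,66.45554787
0.57,67.73586405
0.58,69.64971798
0.59,72.02386405
0.6,74.64
0.61,77.25613595
0.62,79.63028202
0.63,81.54413595
0.64,82.82445213
0.65,83.36
0.66,83.11245213
0.67,82.12013595
0.68,80.49428202
0.69,78.40813595
0.7,76.08
0.71,73.75186405
0.72,71.66571798
0.73,70.03986405
0.74,69.04754787
0.75,68.8
0.76,69.33554787
0.77,70.61586405
0.78,72.52971798
0.79,74.90386405
0.8,77.52
0.81,80.13613595
0.82,82.51028202
0.83,84.42413595
0.84,85.70445213
0.85,86.24
0.86,85.99245213
0.87,85.00013595
0.88,83.37428202
0.89,81.28813595
0.9,78.96
0.91,76.63186405
0.92,74.54571798
0.93,72.91986405
0.94,71.92754787
0.95,71.68
0.96,72.21554787
0.97,73.49586405
0.98,75.40971798
0.99,77.78386405
1.0,80.4
1.01,83.01613595
1.02,85.39028202
1.03,87.30413595
1.04,88.58445213
1.05,89.12
1.06,88.87245213
1.07,87.88013595
1.08,86.25428202
1.09,84.16813595
1.1,81.84
1.11,79.51186405
1.12,77.42571798
1.13,75.79986405
1.14,74.80754787
1.15,74.56
1.16,75.09554787
1.17,76.37586405
1.18,78.28971798
1.19,80.66386405
1.2,83.28
1.21,85.89613595
1.22,88.27028202
1.23,90.18413595
1.24,91.46445213
1.25,92
1.26,91.43245213
1.27,90.12013595
1.28,88.17428202
1.29,85.76813595
1.3,83.12
1.31,80.47186405
1.32,78.06571798
1.33,76.11986405
1.34,74.80754787
1.35,74.24
1.36,74.45554787
1.37,75.41586405
1.38,77.00971798
1.39,79.06386405
1.4,81.36
1.41,83.65613595
1.42,85.71028202
1.43,87.30413595
1.44,88.26445213
1.45,88.48
1.46,87.91245213
1.47,86.60013595
1.48,84.65428202
1.49,82.24813595
1.5,79.6
1.51,76.95186405
1.52,74.54571798
1.53,72.59986405
1.54,71.28754787
1.55,70.72
1.56,70.93554787
1.57,71.89586405
1.58,73.48971798
1.59,75.54386405
1.6,77.84
1.61,80.13613595
1.62,82.19028202
1.63,83.78413595
1.64,84.74445213
1.65,84.96
1.66,84.39245213
1.67,83.08013595
1.68,81.13428202
1.69,78.72813595
1.7,76.08
1.71,73.43186405
1.72,71.02571798
1.73,69.07986405
1.74,67.76754787
1.75,67.2
1.76,67.41554787
1.77,68.37586405
1.78,69.96971798
1.79,72.02386405
1.8,74.32
1.81,76.61613595
1.82,78.67028202
1.83,80.26413595
1.84,81.22445213
1.85,81.44
1.86,80.87245213
1.87,79.56013595
1.88,77.61428202
1.89,75.20813595
1.9,72.56
1.91,69.91186405
1.92,67.50571798
1.93,65.55986405
1.94,64.24754787
1.95,63.68
1.96,63.89554787
1.97,64.85586405
1.98,66.44971798
1.99,68.50386405
2.0,70.8
2.01,73.09613595
2.02,75.15028202
2.03,76.74413595
2.04,77.70445213
2.05,77.92
2.06,77.35245213
2.07,76.04013595
2.08,74.09428202
2.09,71.68813595
2.1,69.04
2.11,66.39186405
2.12,63.98571798
2.13,62.03986405
2.14,60.72754787
2.15,60.16
2.16,60.37554787
2.17,61.33586405
2.18,62.92971798
2.19,64.98386405
2.2,67.28
2.21,69.57613595
2.22,71.63028202
2.23,73.22413595
2.24,74.18445213
2.25,74.4
2.26,73.83245213
2.27,72.52013595
2.28,70.57428202
2.29,68.16813595
2.3,65.52
2.31,62.87186405
2.32,60.46571798
2.33,58.51986405
2.34,57.20754787
2.35,56.64
2.36,56.85554787
2.37,57.81586405
2.38,59.40971798
2.39,61.46386405
2.4,63.76
2.41,66.05613595
2.42,68.11028202
2.43,69.70413595
2.44,70.66445213
2.45,70.88
2.46,70.31245213
2.47,69.00013595
2.48,67.05428202
2.49,64.64813595
2.5,62
2.51,59.65586405
2.52,57.55371798
2.53,55.91186405
2.54,54.90354787
2.55,54.64
2.56,55.15954787
2.57,56.42386405
2.58,58.32171798
2.59,60.67986405
2.6,63.28
2.61,65.88013595
2.62,68.23828202
2.63,70.13613595
2.64,71.40045213
2.65,71.92
2.66,71.65645213
2.67,70.64813595
2.68,69.00628202
2.69,66.90413595
2.7,64.56
2.71,62.21586405
2.72,60.11371798
2.73,58.47186405
2.74,57.46354787
2.75,57.2
2.76,57.71954787
2.77,58.98386405
2.78,60.88171798
2.79,63.23986405
2.8,65.84
2.81,68.44013595
2.82,70.79828202
2.83,72.69613595
2.84,73.96045213
2.85,74.48
2.86,74.21645213
2.87,73.20813595
2.88,71.56628202
2.89,69.46413595
2.9,67.12
2.91,64.77586405
2.92,62.67371798
2.93,61.03186405
2.94,60.02354787
2.95,59.76
2.96,60.27954787
2.97,61.54386405
2.98,63.44171798
2.99,65.79986405
3.0,68.4
3.01,71.00013595
3.02,73.35828202
3.03,75.25613595
3.04,76.52045213
3.05,77.04
3.06,76.77645213
3.07,75.76813595
3.08,74.12628202
3.09,72.02413595
3.1,69.68
3.11,67.33586405
3.12,65.23371798
3.13,63.59186405
3.14,62.58354787
3.15,62.32
3.16,62.83954787
3.17,64.10386405
3.18,66.00171798
3.19,68.35986405
3.2,70.96
3.21,73.56013595
3.22,75.91828202
3.23,77.81613595
3.24,79.08045213
3.25,79.6
3.26,79.33645213
3.27,78.32813595
3.28,76.68628202
3.29,74.58413595
3.3,72.24
3.31,69.89586405
3.32,67.79371798
3.33,66.15186405
3.34,65.14354787
3.35,64.88
3.36,65.39954787
3.37,66.66386405
3.38,68.56171798
3.39,70.91986405
3.4,73.52
3.41,76.12013595
3.42,78.47828202
3.43,80.37613595
3.44,81.64045213
3.45,82.16
3.46,81.89645213
3.47,80.88813595
3.48,79.24628202
3.49,77.14413595
3.5,74.8
3.51,72.45586405
3.52,70.35371798
3.53,68.71186405
3.54,67.70354787
3.55,67.44
3.56,67.95954787
3.57,69.22386405
3.58,71.12171798
3.59,73.47986405
3.6,76.08
3.61,78.68013595
3.62,81.03828202
3.63,82.93613595
3.64,84.20045213
3.65,84.72
3.66,84.45645213
3.67,83.44813595
3.68,81.80628202
3.69,79.70413595
3.7,77.36
3.71,75.01586405
3.72,72.91371798
3.73,71.27186405
3.74,70.26354787
3.75,70
3.76,70.32754787
3.77,71.39986405
3.78,73.10571798
3.79,75.27186405
3.8,77.68
3.81,80.08813595
3.82,82.25428202
3.83,83.96013595
3.84,85.03245213
3.85,85.36
3.86,84.90445213
3.87,83.70413595
3.88,81.87028202
3.89,79.57613595
3.9,77.04
3.91,74.50386405
3.92,72.20971798
3.93,70.37586405
3.94,69.17554787
3.95,68.72
3.96,69.04754787
3.97,70.11986405
3.98,71.82571798
3.99,73.99186405
4.0,76.4
4.01,78.80813595
4.02,80.97428202
4.03,82.68013595
4.04,83.75245213
4.05,84.08
4.06,83.62445213
4.07,82.42413595
4.08,80.59028202
4.09,78.29613595
4.1,75.76
4.11,73.22386405
4.12,70.92971798
4.13,69.09586405
4.14,67.89554787
4.15,67.44
4.16,67.76754787
4.17,68.83986405
4.18,70.54571798
4.19,72.71186405
4.2,75.12
4.21,77.52813595
4.22,79.69428202
4.23,81.40013595
4.24,82.47245213
4.25,82.8
4.26,82.34445213
4.27,81.14413595
4.28,79.31028202
4.29,77.01613595
4.3,74.48
4.31,71.94386405
4.32,69.64971798
4.33,67.81586405
4.34,66.61554787
4.35,66.16
4.36,66.48754787
4.37,67.55986405
4.38,69.26571798
4.39,71.43186405
4.4,73.84
4.41,76.24813595
4.42,78.41428202
4.43,80.12013595
4.44,81.19245213
4.45,81.52
4.46,81.06445213
4.47,79.86413595
4.48,78.03028202
4.49,75.73613595
4.5,73.2
4.51,70.66386405
4.52,68.36971798
4.53,66.53586405
4.54,65.33554787
4.55,64.88
4.56,65.20754787
4.57,66.27986405
4.58,67.98571798
4.59,70.15186405
4.6,72.56
4.61,74.96813595
4.62,77.13428202
4.63,78.84013595
4.64,79.91245213
4.65,80.24
4.66,79.78445213
4.67,78.58413595
4.68,76.75028202
4.69,74.45613595
4.7,71.92
4.71,69.38386405
4.72,67.08971798
4.73,65.25586405
4.74,64.05554787
4.75,63.6
4.76,63.92754787
4.77,64.99986405
4.78,66.70571798
4.79,68.87186405
4.8,71.28
4.81,73.68813595
4.82,75.85428202
4.83,77.56013595
4.84,78.63245213
4.85,78.96
4.86,78.50445213
4.87,77.30413595
4.88,75.47028202
4.89,73.17613595
4.9,70.64
4.91,68.10386405
4.92,65.80971798
4.93,63.97586405
4.94,62.77554787
4.95,62.32
4.96,62.64754787
4.97,63.71986405
4.98,65.42571798
4.99,67.59186405
5.0,70
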