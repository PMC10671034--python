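qtl,chromosome,an,main_neglog10p,main_r2,qei_neglog10p,qei_r2
q-DLP-01-1,1,2,1.66,0.08,,
q-DLP-01-2,1,2,1.55,0.07,4.24,0.28
q-DLP-01-3,1,2,2.84,0.15,,
q-DLP-01-4,1,5,4.71,0.39,,
q-DLP-01-5,1,2,,,1.42,0.09
q-DLP-01-6,1,4,8.56,0.62,4.84,0.46
q-DLP-01-7,1,2,3.54,0.19,,
q-DLP-02-1,2,6,1.41,0.17,4.83,0.58
q-DLP-02-2,2,4,1.67,0.14,2.77,0.30
q-DLP-02-3,2,2,9.45,0.57,,
q-DLP-02-4,2,2,2.78,0.14,2.17,0.14
q-DLP-02-5,2,5,9.32,0.71,1.85,0.27
q-DLP-02-6,2,2,,,3.57,0.24
q-DLP-02-7,2,2,2.92,0.15,4.10,0.27
q-DLP-03-1,3,3,4.10,0.27,1.79,0.17
q-DLP-03-2,3,2,2.87,0.15,,
q-DLP-04-1,4,2,1.97,0.09,1.81,0.12
q-DLP-04-2,4,2,,,2.44,0.16
q-DLP-05-1,5,2,,,2.29,0.15
q-DLP-05-2,5,2,,,3.73,0.25
q-DLP-06-1,6,3,7.14,0.47,,
q-DLP-06-2,6,2,1.59,0.07,2.03,0.13
q-DLP-06-3,6,2,4.66,0.26,3.82,0.25
q-DLP-06-4,6,2,,,1.87,0.12
q-DLP-06-5,6,2,5.01,0.28,4.74,0.31
q-DLP-06-6,6,7,8.74,0.75,2.67,0.44
q-DLP-06-7,6,2,9.00,0.54,3.28,0.22
q-DLP-06-8,6,2,,,2.27,0.15
q-DLP-07-1,7,2,2.92,0.15,,
q-DLP-07-2,7,2,,,2.67,0.18
q-DLP-07-3,7,2,,,3.78,0.25
q-DLP-08-1,8,3,2.87,0.19,2.59,0.23
q-DLP-08-2,8,6,29.24,2.16,3.60,0.48
q-DLP-08-3,8,5,11.46,0.86,2.68,0.35
q-DLP-08-4,8,2,1.33,0.06,,
q-DLP-08-5,8,2,,,1.86,0.12
q-DLP-08-6,8,2,11.21,0.68,,
q-DLP-08-7,8,2,24.2,1.55,,
q-DLP-08-8,8,5,8.59,0.66,4.50,0.50
q-DLP-10-1,10,4,10.64,0.76,2.8,0.31
q-DLP-10-2,10,2,,,5.01,0.33
q-DLP-10-3,10,2,14.02,0.87,,
q-DLP-10-4,10,6,19.29,1.46,2.90,0.42
q-DLP-10-5,10,2,3.60,0.19,,
q-DLP-10-6,10,2,,,2.03,0.13
q-DLP-10-7,10,2,,,6.21,0.41
q-DLP-11-1,11,2,,,3.01,0.20
q-DLP-11-2,11,5,2.56,0.23,,
q-DLP-11-3,11,2,,,2.04,0.13
q-DLP-12-1,12,2,5.98,0.34,,
q-DLP-12-2,12,2,2.71,0.14,,
q-DLP-12-3,12,2,1.87,0.09,,
q-DLP-12-4,12,5,71.48,5.16,2.43,0.33
q-DLP-12-5,12,2,,,2.38,0.16
q-DLP-12-6,12,2,6.53,0.38,,
q-DLP-12-7,12,2,5.37,0.30,2.71,0.18
q-DLP-12-8,12,2,2.48,0.12,3.44,0.23
q-DLP-13-1,13,2,13.42,0.83,,
q-DLP-13-2,13,2,2.69,0.14,,
q-DLP-13-3,13,11,22.1,1.88,7.25,1.06
q-DLP-13-4,13,2,6.05,0.35,2.84,0.19
q-DLP-13-5,13,2,,,3.10,0.20
q-DLP-13-6,13,2,5.67,0.32,,
q-DLP-13-7,13,2,,,7.12,0.47
q-DLP-13-8,13,3,14.96,1.00,2.52,0.23
q-DLP-14-1,14,7,17.82,1.40,2.95,0.47
q-DLP-14-2,14,2,1.98,0.09,,
q-DLP-14-3,14,2,3.25,0.17,,
q-DLP-15-1,15,2,35.9,2.35,1.86,0.12
q-DLP-15-2,15,4,43.98,3.08,8.68,0.75
q-DLP-15-3,15,2,3.87,0.21,5.13,0.34
q-DLP-15-4,15,2,,,1.98,0.13
q-DLP-17-1,17,4,27.4,1.91,4.60,0.45
q-DLP-17-2,17,2,1.33,0.06,2.27,0.15
q-DLP-18-1,18,2,,,2.44,0.16
q-DLP-18-2,18,2,2.06,0.10,3.79,0.25
q-DLP-18-3,18,2,6.62,0.38,,
q-DLP-18-4,18,7,32.42,2.44,,
q-DLP-18-5,18,2,3.75,0.20,1.31,0.09
q-DLP-18-6,18,2,2.81,0.14,,
q-DLP-18-7,18,2,1.67,0.08,3.14,0.21
q-DLP-19-1,19,4,15.13,1.07,3.76,0.38
q-DLP-19-2,19,2,2.46,0.12,2.35,0.16
q-DLP-19-3,19,2,2.33,0.11,,
q-DLP-20-1,20,2,2.02,0.10,,
q-DLP-20-2,20,3,13.17,0.88,,
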