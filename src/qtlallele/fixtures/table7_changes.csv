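qtl,r2,allele,effect,freq_entire,freq_sv,freq_mrv,freq_rv,freq_mrv_rv,gene,category
q-DLP-01-7,0.19,a1,-7.01,1.08,0,0.90,2.70,1.35,Glyma01g41110,IV
q-DLP-02-1,0.17,a4,-0.26,2.97,0,3.15,5.41,3.72,Glyma02g02860,II
q-DLP-02-4,0.14,a1,-2.35,1.35,0,2.25,0,1.69,,
q-DLP-02-5,0.71,a3,0.36,6.22,0,4.05,18.92,7.77,,
q-DLP-02-7,0.15,a2,4.92,1.62,2.70,1.80,0,1.35,Glyma02g48060,V
q-DLP-04-1,0.09,a2,2.65,1.35,2.70,1.35,0,1.01,Glyma04g09220,VIII
q-DLP-06-3,0.26,a2,7.47,1.35,4.05,0.90,0,0.68,,
q-DLP-06-6,0.75,a1,-7.95,1.35,0,1.80,1.35,1.69,Glyma06g33880,III
q-DLP-06-6,0.75,a2,-1.42,1.89,1.35,2.70,0,2.03,Glyma06g33880,III
q-DLP-06-6,0.75,a7,5.88,1.89,2.70,2.25,0,1.69,Glyma06g33880,III
q-DLP-08-4,0.06,a1,-2.76,1.08,0,0.90,2.70,1.35,,
q-DLP-08-7,1.55,a1,-11.02,2.16,0,0.90,8.11,2.70,Glyma08g43830,V
q-DLP-08-8,0.66,a5,4.76,1.35,4.05,0.90,0,0.68,Glyma08g45950,I
q-DLP-10-1,0.76,a1,-5.06,5.68,0,6.76,8.11,7.09,Glyma10g03140,II
q-DLP-10-1,0.76,a2,-1.41,2.70,0,1.80,8.11,3.38,Glyma10g03140,II
q-DLP-10-3,0.87,a2,7.38,1.35,4.05,0.90,0,0.68,Glyma10g05160,II
q-DLP-10-4,1.46,a1,-6.51,1.89,0,1.35,5.41,2.36,Glyma10g19710,VIII
q-DLP-10-4,1.46,a6,5.92,1.08,0,1.35,1.35,1.35,Glyma10g19710,VIII
q-DLP-11-2,0.23,a5,4.46,2.43,4.05,2.70,0,2.03,Glyma11g28580,VIII
q-DLP-12-6,0.38,a2,7.09,1.08,2.70,0.90,0,0.68,,
q-DLP-12-7,0.30,a2,6.38,1.08,4.05,0,1.35,0.34,,
q-DLP-12-8,0.12,a2,2.53,1.89,2.70,2.25,0,1.69,Glyma12g28490,II
q-DLP-13-1,0.83,a1,-8.46,1.08,0,0.45,4.05,1.35,,
q-DLP-13-3,1.88,a1,-6.53,1.62,0,1.35,4.05,2.03,Glyma13g10070,II
q-DLP-13-3,1.88,a10,5.06,2.70,2.70,3.60,0,2.70,Glyma13g10070,II
q-DLP-13-3,1.88,a11,6.60,2.70,0,2.70,5.41,3.38,Glyma13g10070,II
q-DLP-14-1,1.40,a7,3.65,1.35,0,1.80,1.35,1.69,Glyma14g13792,III
q-DLP-17-2,0.06,a2,2.42,1.62,2.70,1.80,0,1.35,Glyma17g29620,III
q-DLP-18-3,0.38,a2,7.88,1.08,1.35,1.35,0,1.01,Glyma18g46050,I
q-DLP-18-4,2.44,a6,5.93,1.35,0,1.35,2.70,1.69,Glyma18g46220,I
q-DLP-19-2,0.12,a2,2.75,1.35,0,2.25,0,1.69,Glyma19g36280,II
q-DLP-19-3,0.11,a2,2.92,1.62,2.70,1.80,0,1.35,Glyma19g41400,III
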