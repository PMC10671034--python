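qtl,position,gene,go_description,category,lc
q-DLP-01-1,2018307,Glyma01g02525,Xylan biosynthetic process,II,0
q-DLP-01-2,45358479,,,,0
q-DLP-01-3,48727687,Glyma01g36200,Response to salicylic acid stimulus,I,0
q-DLP-01-4,49414457_49512678,Glyma01g37020,Regulation of meristem growth,VI,0
q-DLP-01-5,50563918_50575958,Glyma01g38470,Response to auxin stimulus,I,0
q-DLP-01-6,51562541_51627699,Glyma01g39590,Xylan biosynthetic process,II,0
q-DLP-01-7,52647305,Glyma01g41110,Hormone-mediated signaling pathway,IV,0
q-DLP-02-1,1973000_2157204,Glyma02g02860,Toxin catabolic process,II,0
q-DLP-02-2,4018617_4025103,Glyma02g04965,Response to chitin,I,0
q-DLP-02-3,14648440_14667968,Glyma02g16260,Response to abscisic acid stimulus,I,0
q-DLP-02-4,17944684,,,,0
q-DLP-02-5,25406263_25479114,,,,0
q-DLP-02-6,29142262_29263830,Glyma02g27950,Unknown process,VIII,0
q-DLP-02-7,51455660,Glyma02g48060,Transmembrane transport,V,0
q-DLP-03-1,5122536_5122820,Glyma03g04920,Lipid transport,V,0
q-DLP-03-2,14208130,,,,0
q-DLP-04-1,7402649,Glyma04g09220,Unknown process,VIII,0
q-DLP-04-2,46268205_46268222,Glyma04g40121,"Regulation of transcription, DNA-dependent",VII,0
q-DLP-05-1,18014789,,,,0
q-DLP-05-2,24588612,,,,0
q-DLP-06-1,420122_487621,Glyma06g00730,Response to insect,I,0
q-DLP-06-2,22275863,Glyma06g24701,Unknown process,VIII,0
q-DLP-06-3,24692151,,,,0
q-DLP-06-4,29026459,,,,0
q-DLP-06-5,32468737,,,,0
q-DLP-06-6,35040678_35236874,Glyma06g33880,Protein glycosylation,III,0
q-DLP-06-7,44178948,,,,0
q-DLP-06-8,50304823_50305172,Glyma06g47920,Unknown process,VIII,0
q-DLP-07-1,28717244,,,,0
q-DLP-07-2,36293327_36297011,Glyma07g31320,Protein complex assembly,III,0
q-DLP-07-3,40096883,Glyma07g35023,Unknown process,VIII,0
q-DLP-08-1,14753730_14760906,Glyma08g19560,Response to wounding,I,0
q-DLP-08-2,14777419_14822821,Glyma08g19650,Sugar-mediated signaling pathway,IV,1
q-DLP-08-3,22259705_22457223,Glyma08g28111,"Transcription, DNA-dependent",VII,0
q-DLP-08-4,31137298,,,,0
q-DLP-08-5,40375262,Glyma08g40646,Signal transduction,IV,0
q-DLP-08-6,41582869,Glyma08g41670,Hydrogen peroxide biosynthetic process,II,0
q-DLP-08-7,43612649,Glyma08g43830,Transmembrane transport,V,1
q-DLP-08-8,45217877_45266178,Glyma08g45950,Response to wounding,I,0
q-DLP-10-1,2137913_2266216,Glyma10g03140,Regulation of flavonoid biosynthetic process,II,0
q-DLP-10-2,2777471,Glyma10g03720,Response to jasmonic acid stimulus,I,0
q-DLP-10-3,4019592,Glyma10g05160,Xylan biosynthetic process,II,0
q-DLP-10-4,24526775_24706774,Glyma10g19710,Unknown process,VIII,1
q-DLP-10-5,39555777,Glyma10g30930,Unknown process,VIII,0
q-DLP-10-6,45227388,,,,0
q-DLP-10-7,46996455,Glyma10g39250,Unknown process,VIII,0
q-DLP-11-1,4931380,Glyma11g07080,Indoleacetic acid biosynthetic process,II,0
q-DLP-11-2,28787840_28938957,Glyma11g28580,Unknown process,VIII,0
q-DLP-11-3,35388102,,,,0
q-DLP-12-1,4069210_4160826,Glyma12g05960,Sugar-mediated signaling pathway,IV,0
q-DLP-12-2,5802081,Glyma12g08080,Regulation of meristem growth,VI,0
q-DLP-12-3,6664148_6664175,Glyma12g08900,Response to oxidative stress,I,0
q-DLP-12-4,10441681_10513287,,,,1
q-DLP-12-5,14076555,,,,0
q-DLP-12-6,21170928,,,,0
q-DLP-12-7,28906122,,,,0
q-DLP-12-8,31830778,Glyma12g28490,Selenium compound metabolic process,II,0
q-DLP-13-1,5519025,,,,0
q-DLP-13-2,7661807_7661825,Glyma13g07530,Unknown process,VIII,0
q-DLP-13-3,11608283_11644846,Glyma13g10070,Positive regulation of flavonoid biosynthetic process,II,1
q-DLP-13-4,16616018_16616049,,,,0
q-DLP-13-5,22285871,,,,0
q-DLP-13-6,22414892,Glyma13g18720,Plant-type cell wall modification,VI,0
q-DLP-13-7,25945441,Glyma13g22450,Sugar-mediated signaling pathway,IV,0
q-DLP-13-8,29302932_29302990,Glyma13g26030,Unknown process,VIII,1
q-DLP-14-1,13354054_13553649,Glyma14g13792,Histone H3-K4 methylation,III,1
q-DLP-14-2,15737492,Glyma14g14990,Jasmonic acid biosynthetic process,II,0
q-DLP-14-3,43771273,,,,0
q-DLP-15-1,1215528,Glyma15g01790,Protein ubiquitination,III,1
q-DLP-15-2,42911867_42923525,Glyma15g37276,Defense response to fungus,I,1
q-DLP-15-3,47989791_47999025,Glyma15g41020,Regulation of meristem growth,VI,0
q-DLP-15-4,48785322_48785485,Glyma15g41640,Oxidation-reduction process,II,0
q-DLP-17-1,13426556_13441932,Glyma17g16641,"Regulation of transcription, DNA-dependent",VII,1
q-DLP-17-2,32299189,Glyma17g29620,Protein N-linked glycosylation,III,0
q-DLP-18-1,3801888,Glyma18g05090,Positive regulation of cell proliferation,VI,0
q-DLP-18-2,12477590,,,,0
q-DLP-18-3,55745667,Glyma18g46050,Defense response,I,0
q-DLP-18-4,55988107_55988755,Glyma18g46220,Response to cold,I,1
q-DLP-18-5,56055671,Glyma18g46286,Transmembrane transport,V,0
q-DLP-18-6,58793224,Glyma18g49390,Unknown process,VIII,0
q-DLP-18-7,60245212,Glyma18g51380,Polyamine biosynthetic process,II,0
q-DLP-19-1,5454340_5454561,,,,1
q-DLP-19-2,43592061,Glyma19g36280,Xylan biosynthetic process,II,0
q-DLP-19-3,47642370,Glyma19g41400,Protein glycosylation,III,0
q-DLP-20-1,16840184,Glyma20g11950,Oxidation-reduction process,II,0
q-DLP-20-2,35128616_35247501,Glyma20g25418,Systemic acquired resistance,I,0
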