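n_links	gene	phenotype	category	accession	notes
93	Rac1	Abnormal testis morphology; small testis	reproductive_system	97845	Proto-oncogene (glioblastoma, melanoma, leukemia, brain, lung, testicular and breast cancers)
38	Itpr1	Small epididymis	reproductive_system	96623	Proto-oncogene (multiple myeloma, breast, lung and renal carcinomas)
36	Ppp1cc	Male infertility	reproductive_system	104872	Proto-oncogene (malignant fibrous histiocytoma, osteogenic and soft tissue tumors)
32	Ube2n	Abnormal seminal vesicle morphology	reproductive_system	1934835	PCOS; proto-oncogene (melanoma, colorectal, cervical, ovarian carcinomas)
27	Med1	Enlarged uterus	reproductive_system	1100846	Tumor suppressor gene (colorectal, gastric, endometrial, pancreatic cancers)
26	Ppp2r1b	Male infertility	reproductive_system	1920949	Azoospermia; tumor suppressor gene (lung, colon, endometrial carcinomas)
24	Plcb1	Male infertility; female infertility; abnormal ovary morphology	reproductive_system	97613	Proto-oncogene (cholangiocarcinoma, colorectal, hepatocellular, ovarian cancers)
20	Afdn	Abnormal uterus morphology	reproductive_system	1314653	Tumor suppressor gene (ALL); proto-oncogene (endometrial, gastric, colon cancers)
18	Skp2	Male infertility; female infertility	reproductive_system	1351663	Proto-oncogene (osteosarcoma, lymphomas, colorectal, breast and prostate cancers)
18	Sacm1l	Enlarged epididymis; abnormal testis morphology; small testis; abnormal epididymis morphology	reproductive_system	1933169	Associated to COVID-19 severity
18	Ccnd2	Small testis	reproductive_system	88314	Tumor suppressor gene (lymphomas, AML) and proto-oncogene (ovarian, testicular, breast cancers)
38	Itpr1	Embryonic growth retardation; abnormal embryo size	embryo	96623	Proto-oncogene (multiple myeloma, breast, lung and renal cancers)
27	Med1	Abnormal placenta size; abnormal embryo size	embryo	1100846	Tumor suppressor gene (colorectal, gastric, endometrial, pancreatic cancers)
24	Ap2b1	Abnormal embryo size	embryo	1919020	Tumor suppressor gene (triple-negative breast cancer); proto-oncogene (prostate cancer)
24	Ubxn7	Abnormal embryo size; embryonic growth retardation	embryo	2146388	Proto-oncogene (lung squamous cell carcinoma)
21	Cacna1c	Abnormal placenta morphology	embryo	103013	Proto-oncogene (leukemia, breast, brain tumors); tumor suppressor (ovarian, endometrial cancers)
21	Plod2	Abnormal embryo size	embryo	1347007	Proto-oncogene (breast, colorectal, lung, bladder, cervical, ovarian, renal and bone cancers)
20	Afdn	Abnormal neural tube morphology; abnormal neural tube closure	embryo	1314653	Tumor suppressor gene (ALL); proto-oncogene (endometrial, gastric, colon cancers)
20	Gna13	Abnormal visceral yolk sac morphology; abnormal embryo size	embryo	95768	Proto-oncogene (B-cell lymphoma; ovarian, prostate, colorectal and gastric cancers)
20	Ncoa2	Abnormal umbilical cord morphology; abnormal placenta vasculature	embryo	1276533	Translocations in various cancers (AML, ALL; mesenchymal chondrosarcoma)
19	Arhgef12	Abnormal embryo size; embryonic growth retardation	embryo	1916882	Glaucoma; tumor suppressor gene (AML, lymphomas, pancreatic cancer)
19	Bmi1	Abnormal embryo size	embryo	88174	Proto-oncogene (breast, gastric, ovarian, lung, pancreatic cancers)
18	Dnmt3a	Abnormal embryo size	embryo	1261827	Tumor suppressor gene (AML, leukemia); proto-oncogene (testicular tumor)
17	Acvr2a	Abnormal embryo size	embryo	102806	Susceptibility to preeclampsia; tumor suppressor gene (hepatocellular carcinoma)
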