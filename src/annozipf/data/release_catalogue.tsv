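swissprot_date	swissprot_version	trembl_date	trembl_version
1996-10	34	1996-11	1
1997-11	35	1998-01	5
1998-07	36	1998-08	7
1998-12	37	1999-01	9
1999-07	38	1999-08	11
2000-05	39	2000-05	13
2001-10	40	2001-10	18
2003-02	41	2003-03	23
2003-10	42	2003-10	25
2004-03	43	2004-03	26
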