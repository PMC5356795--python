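reported_id	official_id	year	regulation	sample_type	method	nod
miR-630	miR-630	2011	up	tissue	qRT-PCR	5
miR-622	miR-622	2011	up	tissue	qRT-PCR	1
miR-483-5p	miR-483-5p	2011	up	tissue	qRT-PCR	4
miR-125a-3p	miR-125a-3p	2011	up	tissue	qRT-PCR	2
miR-188-5p	miR-188-5p	2011	up	tissue	qRT-PCR	1
miR-671-5p	miR-671-5p	2011	up	tissue	qRT-PCR	10
miR-765	miR-765	2011	up	tissue	qRT-PCR	10
miR-196b	miR-196b-5p	2012	up	tissue	TLDA	12
let-7e	let-7e-5p	2012	up	tissue	TLDA	2
miR-223	miR-223-3p	2012	up	tissue	qRT-PCR	9
let-7a	let-7a-5p	2013	up	cell lines	qRT-PCR	5
miR-21	miR-21-5p	2013	up	cell lines	qRT-PCR	38
miR-221	miR-221-3p	2013	up	cell lines	qRT-PCR	11
miR-132	miR-132-3p	2013	up	cell lines and tissue	qRT-PCR	8
miR-224	miR-224-5p	2013	up	cell lines and tissue	qRT-PCR	13
let-7g	let-7g-5p	2013	up	cell lines and tissue	qRT-PCR	17
miR-125b	miR-125b-5p	2008	down	tissue	qRT-PCR	33
miR-137	miR-137	2008	down	tissue	qRT-PCR	17
miR-451	miR-451a	2009	down	cell lines and tissue	qRT-PCR	4
miR-143	miR-143-3p	2011	down	tissue	qRT-PCR	15
miR-145	miR-145-5p	2011	down	tissue	qRT-PCR	36
miR-215	miR-215	2012	down	tissue	TLDA	1
miR-200c	miR-200c-3p	2013	down	tissue	qRT-PCR	13
miR-320a	miR-320a	2013	down	cell lines and tissue	qRT-PCR	15
miR-124	miR-124-3p	2014	down	cell lines and tissue	qRT-PCR	51
miR-16	miR-16-5p	2012	NA	tissue	qRT-PCR	7
miR-590-5p	miR-590-5p	2012	NA	tissue	qRT-PCR	14
miR-153	miR-153	2012	NA	tissue	qRT-PCR	1
miR-519c-3p	miR-519c-3p	2012	NA	tissue	qRT-PCR	1
miR-561	miR-561-3p	2012	NA	tissue	qRT-PCR	15
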