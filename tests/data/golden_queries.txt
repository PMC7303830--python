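D003924	A	-	"diabetes mellitus, type 2"[mh]
D003924	B	ATM	"diabetes mellitus, type 2"[tiab] AND medline[sb]
D003924	C	ATM	"diabetes mellitus, type 2"[mh] AND "diabetes mellitus, type 2"[tiab] AND medline[sb]
D003924	B	MESH	("diabetes mellitus, type 2"[tiab] OR "diabetes mellitus, noninsulin-dependent"[tiab] OR "niddm"[tiab]) AND medline[sb]
D003924	C	MESH	"diabetes mellitus, type 2"[mh] AND ("diabetes mellitus, type 2"[tiab] OR "diabetes mellitus, noninsulin-dependent"[tiab] OR "niddm"[tiab]) AND medline[sb]
D003924	B	UMLS	("adult onset diabetes"[tiab] OR "adult onset diabetes mellitus"[tiab] OR "adult-onset diabetes"[tiab] OR "adult-onset diabetes mellitus"[tiab]) AND medline[sb]
D003924	C	UMLS	"diabetes mellitus, type 2"[mh] AND ("adult onset diabetes"[tiab] OR "adult onset diabetes mellitus"[tiab] OR "adult-onset diabetes"[tiab] OR "adult-onset diabetes mellitus"[tiab]) AND medline[sb]
D003924	B	CISMEF	"type 2 diabetes"[tiab] AND medline[sb]
D003924	C	CISMEF	"diabetes mellitus, type 2"[mh] AND "type 2 diabetes"[tiab] AND medline[sb]
D002908	A	-	"chronic disease"[mh]
D002908	B	ATM	"chronic disease"[tiab] AND medline[sb]
D002908	C	ATM	"chronic disease"[mh] AND "chronic disease"[tiab] AND medline[sb]
D002908	B	MESH	"chronic disease"[tiab] AND medline[sb]
D002908	C	MESH	"chronic disease"[mh] AND "chronic disease"[tiab] AND medline[sb]
D002908	B	UMLS	("chronic illness"[tiab] OR "chronically ill"[tiab]) AND medline[sb]
D002908	C	UMLS	"chronic disease"[mh] AND ("chronic illness"[tiab] OR "chronically ill"[tiab]) AND medline[sb]
D002908	B	CISMEF	("chronic disease"[tiab] OR "chronic"[tiab]) AND medline[sb]
D002908	C	CISMEF	"chronic disease"[mh] AND ("chronic disease"[tiab] OR "chronic"[tiab]) AND medline[sb]
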