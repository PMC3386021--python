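"Gene","Non-unique Gene name","Annotation","No. isolates","iso1","iso2","iso3"
"group_0001","","hypothetical protein","3","iso1_00010","iso2_00012","iso3_00007"
"group_0002","dnaA","chromosomal replication initiator","2","iso1_00001","","iso3_00001"
"group_0003","","phage integrase","1","","iso2_00044",""
"group_0004","recA","recombinase A","3","iso1_00220","iso2_00218","iso3_00224"
"group_0005","","ABC transporter","1","iso1_00310","",""
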