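>hsa-miR-375 mature sequence, miRBase MIMAT0000728
UUUGUUCGUUCGGCUCGCGUGA
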