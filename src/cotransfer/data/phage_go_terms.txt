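# Synthetic default list of phage/mobile-element-associated GO terms.
# Placeholder vocabulary matching the synthetic-data generator; supply a
# curated list (e.g. from an AmiGO query for "phage"/"mobile element") for
# real annotations.
GO:PHAGE_CAPSID
GO:PHAGE_TAIL
GO:PHAGE_INTEGRATION
GO:PHAGE_LYSIS
GO:PHAGE_REPLICATION
GO:PHAGE_PORTAL
GO:PHAGE_TERMINASE
GO:MOBILE_ELEMENT
GO:TRANSPOSITION
GO:PROPHAGE_EXCISION
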