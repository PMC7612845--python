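# Default cluster -> group mapping for the synthetic HSPC landscape
# produced by emh.simulate.default_hspc_config.  Real datasets use their
# own mapping; cluster labels are never hard-coded in the library.
HSC/MPP: HSC/MPP
MEMB-early: early MEMB
MEMB-mid: late MEMB
MEMB-late: late MEMB
My-early: early My
My-late: late My
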