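# Compounds retained despite failing the default ADME thresholds
# (literature-reported anti-inflammatory / antioxidant / anticancer /
# antibacterial activity), one compound_id per line.
C1
C2
C4
C6
C10
C11
C12
C14
C15
C19
C22
C23
C25
C32
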