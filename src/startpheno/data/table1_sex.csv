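group,F,M
TD,19,21
AS,12,36
ID,9,34
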