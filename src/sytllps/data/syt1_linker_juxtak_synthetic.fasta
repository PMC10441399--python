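>syt1_linker_juxtak_synthetic synthetic JuxtaK reconstruction: all linker lysines except K141 substituted K->Q
QQCLFQQQNQQQGQEQGGQNAINMQDVQDLGQTMQDQALQDDDAETGLTDGEEQEEPQEE
EKL
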