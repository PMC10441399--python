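>syt1_linker_wt rat synaptotagmin-1 (UniProt P21707) residues 80-142
KKCLFKKKNKKKGKEKGGKNAINMKDVKDLGKTMKDQALKDDDAETGLTDGEEKEEPKEE
EKL
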