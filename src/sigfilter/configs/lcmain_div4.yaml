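# Frozen LightCall configuration "lcmain_div4" (do not edit: parameter counts
# are part of the package contract).
name: lcmain_div4
n_blocks: 9
width: 69
kernel: 9
groups: null
stem_kernel: 33
stem_stride: 3
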