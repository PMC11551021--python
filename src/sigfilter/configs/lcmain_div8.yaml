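# Frozen LightCall configuration "lcmain_div8" (do not edit: parameter counts
# are part of the package contract).
name: lcmain_div8
n_blocks: 6
width: 51
kernel: 9
groups: null
stem_kernel: 33
stem_stride: 3
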