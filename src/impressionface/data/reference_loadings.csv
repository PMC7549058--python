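item,pc1_valence,pc2_dominance
lively/agile,0.25,-0.19
sociable,0.25,-0.15
intelligent/knowledgeable,0.25,0.24
reliable/trustworthy,0.25,-0.05
approachable,0.25,-0.25
beautiful,0.25,0.25
financially fit/rich,0.24,0.22
dignified,0.24,0.32
open-minded,0.24,-0.24
graceful,0.24,0.24
cheerful,0.24,-0.31
humanly,0.23,-0.29
cute,0.23,0.14
fresh/clean,0.23,0.28
not niggled,0.23,-0.04
easily influenced,-0.13,-0.33
tired,-0.22,0.04
irritated,-0.23,0.32
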