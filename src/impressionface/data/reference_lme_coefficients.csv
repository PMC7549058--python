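item,intercept,beta_valence,beta_dominance
lively/agile,46.86,6.55,-0.13
irritated,40.63,-3.51,3.31
cute,40.12,5.62,1.06
beautiful,54.86,7.34,1.87
financially fit/rich,52.82,4.31,0.51
open-minded,47.07,3.84,-4.42
not niggled,54.91,2.37,2.23
sociable,51.98,5.80,-0.89
graceful,56.55,6.35,-0.02
fresh/clean,58.68,5.30,0.43
cheerful,40.76,6.53,-1.73
reliable/trustworthy,54.40,6.17,-0.52
intelligent/knowledgeable,53.89,5.46,1.49
tired,51.60,-6.13,-0.68
humanly,55.99,1.00,-2.58
approachable,48.45,3.70,-3.78
easily influenced,39.45,-3.49,-3.10
dignified,53.70,7.45,1.61
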