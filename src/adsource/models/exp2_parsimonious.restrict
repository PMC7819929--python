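# base restriction set 'exp2_parsimonious'
restrict: D_unknown.high = D_new.high
restrict: D_unknown.low = D_new.low
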