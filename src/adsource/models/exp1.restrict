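# base restriction set 'exp1'
restrict: D_ad.high = D_test.high = D_new.high
restrict: a_ad.high = g_ad.high
restrict: D_ad.low = D_test.low = D_new.low
restrict: a_ad.low = g_ad.low
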