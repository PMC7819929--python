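# base restriction set 'exp1_unrestrictedD'
restrict: a_ad.high = g_ad.high
restrict: a_ad.low = g_ad.low
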