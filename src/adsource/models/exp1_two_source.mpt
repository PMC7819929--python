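# two-source source-monitoring model, high/low a-priori credibility
!categories ad.high: ad test new
!categories test.high: ad test new
!categories new.high: ad test new
!categories ad.low: ad test new
!categories test.low: ad test new
!categories new.low: ad test new
ad.high  ad  D_ad.high * d_ad.high
ad.high  ad  D_ad.high * (1-d_ad.high) * a_ad.high
ad.high  test  D_ad.high * (1-d_ad.high) * (1-a_ad.high)
ad.high  ad  (1-D_ad.high) * b.high * g_ad.high
ad.high  test  (1-D_ad.high) * b.high * (1-g_ad.high)
ad.high  new  (1-D_ad.high) * (1-b.high)
test.high  test  D_test.high * d_test.high
test.high  ad  D_test.high * (1-d_test.high) * a_ad.high
test.high  test  D_test.high * (1-d_test.high) * (1-a_ad.high)
test.high  ad  (1-D_test.high) * b.high * g_ad.high
test.high  test  (1-D_test.high) * b.high * (1-g_ad.high)
test.high  new  (1-D_test.high) * (1-b.high)
new.high  new  D_new.high
new.high  ad  (1-D_new.high) * b.high * g_ad.high
new.high  test  (1-D_new.high) * b.high * (1-g_ad.high)
new.high  new  (1-D_new.high) * (1-b.high)
ad.low  ad  D_ad.low * d_ad.low
ad.low  ad  D_ad.low * (1-d_ad.low) * a_ad.low
ad.low  test  D_ad.low * (1-d_ad.low) * (1-a_ad.low)
ad.low  ad  (1-D_ad.low) * b.low * g_ad.low
ad.low  test  (1-D_ad.low) * b.low * (1-g_ad.low)
ad.low  new  (1-D_ad.low) * (1-b.low)
test.low  test  D_test.low * d_test.low
test.low  ad  D_test.low * (1-d_test.low) * a_ad.low
test.low  test  D_test.low * (1-d_test.low) * (1-a_ad.low)
test.low  ad  (1-D_test.low) * b.low * g_ad.low
test.low  test  (1-D_test.low) * b.low * (1-g_ad.low)
test.low  new  (1-D_test.low) * (1-b.low)
new.low  new  D_new.low
new.low  ad  (1-D_new.low) * b.low * g_ad.low
new.low  test  (1-D_new.low) * b.low * (1-g_ad.low)
new.low  new  (1-D_new.low) * (1-b.low)
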