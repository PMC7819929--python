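# three-source source-monitoring model (stick-breaking guess nodes), high/low credibility
!categories ad.high: ad test unknown new
!categories test.high: ad test unknown new
!categories unknown.high: ad test unknown new
!categories new.high: ad test unknown new
!categories ad.low: ad test unknown new
!categories test.low: ad test unknown new
!categories unknown.low: ad test unknown new
!categories new.low: ad test unknown new
ad.high  ad  D_ad.high * d_ad.high
ad.high  ad  D_ad.high * (1-d_ad.high) * a_ad.high
ad.high  test  D_ad.high * (1-d_ad.high) * (1-a_ad.high) * a_test.high
ad.high  unknown  D_ad.high * (1-d_ad.high) * (1-a_ad.high) * (1-a_test.high)
ad.high  ad  (1-D_ad.high) * b.high * g_ad.high
ad.high  test  (1-D_ad.high) * b.high * (1-g_ad.high) * g_test.high
ad.high  unknown  (1-D_ad.high) * b.high * (1-g_ad.high) * (1-g_test.high)
ad.high  new  (1-D_ad.high) * (1-b.high)
test.high  test  D_test.high * d_test.high
test.high  ad  D_test.high * (1-d_test.high) * a_ad.high
test.high  test  D_test.high * (1-d_test.high) * (1-a_ad.high) * a_test.high
test.high  unknown  D_test.high * (1-d_test.high) * (1-a_ad.high) * (1-a_test.high)
test.high  ad  (1-D_test.high) * b.high * g_ad.high
test.high  test  (1-D_test.high) * b.high * (1-g_ad.high) * g_test.high
test.high  unknown  (1-D_test.high) * b.high * (1-g_ad.high) * (1-g_test.high)
test.high  new  (1-D_test.high) * (1-b.high)
unknown.high  unknown  D_unknown.high * d_unknown.high
unknown.high  ad  D_unknown.high * (1-d_unknown.high) * a_ad.high
unknown.high  test  D_unknown.high * (1-d_unknown.high) * (1-a_ad.high) * a_test.high
unknown.high  unknown  D_unknown.high * (1-d_unknown.high) * (1-a_ad.high) * (1-a_test.high)
unknown.high  ad  (1-D_unknown.high) * b.high * g_ad.high
unknown.high  test  (1-D_unknown.high) * b.high * (1-g_ad.high) * g_test.high
unknown.high  unknown  (1-D_unknown.high) * b.high * (1-g_ad.high) * (1-g_test.high)
unknown.high  new  (1-D_unknown.high) * (1-b.high)
new.high  new  D_new.high
new.high  ad  (1-D_new.high) * b.high * g_ad.high
new.high  test  (1-D_new.high) * b.high * (1-g_ad.high) * g_test.high
new.high  unknown  (1-D_new.high) * b.high * (1-g_ad.high) * (1-g_test.high)
new.high  new  (1-D_new.high) * (1-b.high)
ad.low  ad  D_ad.low * d_ad.low
ad.low  ad  D_ad.low * (1-d_ad.low) * a_ad.low
ad.low  test  D_ad.low * (1-d_ad.low) * (1-a_ad.low) * a_test.low
ad.low  unknown  D_ad.low * (1-d_ad.low) * (1-a_ad.low) * (1-a_test.low)
ad.low  ad  (1-D_ad.low) * b.low * g_ad.low
ad.low  test  (1-D_ad.low) * b.low * (1-g_ad.low) * g_test.low
ad.low  unknown  (1-D_ad.low) * b.low * (1-g_ad.low) * (1-g_test.low)
ad.low  new  (1-D_ad.low) * (1-b.low)
test.low  test  D_test.low * d_test.low
test.low  ad  D_test.low * (1-d_test.low) * a_ad.low
test.low  test  D_test.low * (1-d_test.low) * (1-a_ad.low) * a_test.low
test.low  unknown  D_test.low * (1-d_test.low) * (1-a_ad.low) * (1-a_test.low)
test.low  ad  (1-D_test.low) * b.low * g_ad.low
test.low  test  (1-D_test.low) * b.low * (1-g_ad.low) * g_test.low
test.low  unknown  (1-D_test.low) * b.low * (1-g_ad.low) * (1-g_test.low)
test.low  new  (1-D_test.low) * (1-b.low)
unknown.low  unknown  D_unknown.low * d_unknown.low
unknown.low  ad  D_unknown.low * (1-d_unknown.low) * a_ad.low
unknown.low  test  D_unknown.low * (1-d_unknown.low) * (1-a_ad.low) * a_test.low
unknown.low  unknown  D_unknown.low * (1-d_unknown.low) * (1-a_ad.low) * (1-a_test.low)
unknown.low  ad  (1-D_unknown.low) * b.low * g_ad.low
unknown.low  test  (1-D_unknown.low) * b.low * (1-g_ad.low) * g_test.low
unknown.low  unknown  (1-D_unknown.low) * b.low * (1-g_ad.low) * (1-g_test.low)
unknown.low  new  (1-D_unknown.low) * (1-b.low)
new.low  new  D_new.low
new.low  ad  (1-D_new.low) * b.low * g_ad.low
new.low  test  (1-D_new.low) * b.low * (1-g_ad.low) * g_test.low
new.low  unknown  (1-D_new.low) * b.low * (1-g_ad.low) * (1-g_test.low)
new.low  new  (1-D_new.low) * (1-b.low)
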