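cluster,n,referrer,top1,top2,top3
eczema,1,1,1,1,1
dry_eye,2,1,1,1,1
subconj_blood,1,0,0,0,0
conjunctivitis,4,2,2,2,3
scleritis,4,2,1,2,3
keratitis,16,13,15,15,15
corneal_ulcer,11,10,9,10,10
acute_acg,1,0,0,0,0
iritis,13,9,9,11,12
endophthalmitis,1,1,1,1,1
other,3,1,0,0,0
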