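group,subject,sample,events,trials
None,1,1,4,5
None,1,2,4,5
None,2,1,3,5
None,2,2,4,5
None,2,3,5,5
None,2,4,2,5
None,3,1,2,5
None,3,2,3,5
None,3,3,3,5
None,3,4,2,5
None,4,1,2,5
None,4,2,4,5
None,4,3,1,5
None,4,4,2,5
None,4,5,1,5
None,5,1,3,5
None,5,2,4,5
None,5,3,4,5
None,5,4,3,5
None,5,5,5,5
None,6,1,2,5
None,6,2,5,5
None,6,3,5,5
None,6,4,3,5
None,6,5,3,5
Short RT,7,1,1,5
Short RT,7,2,0,5
Short RT,7,3,0,5
Short RT,7,4,0,5
Short RT,7,5,0,5
Short RT,8,1,1,5
Short RT,8,2,2,5
Short RT,9,1,1,5
Short RT,9,2,0,5
Short RT,9,3,1,5
Short RT,9,4,0,5
Short RT,9,5,2,5
Short RT,10,1,2,5
Short RT,10,2,1,5
Short RT,10,3,4,5
Short RT,10,4,0,5
Short RT,10,5,2,5
Short RT,11,1,4,5
Short RT,11,2,2,5
Short RT,11,3,4,5
Short RT,11,4,3,5
Short RT,11,5,3,5
Short RT,12,1,3,5
Short RT,12,2,4,5
Short RT,12,3,3,5
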