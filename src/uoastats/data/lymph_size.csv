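group,subject,sample,replicate,value
None,1,1,1,1.71
None,1,1,2,1.98
None,1,1,3,1.88
None,1,2,1,1.72
None,1,2,2,1.98
None,1,2,3,1.85
None,2,1,1,2.51
None,2,1,2,2.55
None,2,1,3,2.65
None,2,2,1,2.98
None,2,2,2,3.20
None,2,2,3,2.80
None,3,1,1,1.69
None,3,1,2,1.72
None,3,1,3,1.80
None,3,2,1,1.82
None,3,2,2,1.97
None,3,2,3,1.73
None,4,1,1,1.72
None,4,1,2,1.78
None,4,1,3,2.04
None,4,2,1,2.50
None,4,2,2,2.65
None,4,2,3,2.77
None,5,1,1,3.32
None,5,1,2,3.27
None,5,1,3,3.07
None,5,2,1,3.11
None,5,2,2,3.03
None,5,2,3,3.11
None,6,1,1,2.33
None,6,1,2,2.48
None,6,1,3,2.53
None,6,2,1,2.86
None,6,2,2,2.87
None,6,2,3,2.52
Short RT,7,1,1,2.37
Short RT,7,1,2,2.36
Short RT,7,1,3,2.20
Short RT,7,2,1,2.36
Short RT,7,2,2,2.62
Short RT,7,2,3,2.60
Short RT,8,1,1,1.33
Short RT,8,1,2,1.35
Short RT,8,1,3,1.15
Short RT,8,2,1,1.90
Short RT,8,2,2,1.87
Short RT,8,2,3,1.85
Short RT,9,1,1,1.70
Short RT,9,1,2,1.78
Short RT,9,1,3,1.78
Short RT,9,2,1,2.07
Short RT,9,2,2,1.76
Short RT,9,2,3,1.85
Short RT,10,1,1,2.23
Short RT,10,1,2,2.14
Short RT,10,1,3,2.21
Short RT,10,2,1,2.50
Short RT,10,2,2,2.33
Short RT,10,2,3,2.16
Short RT,11,1,1,2.10
Short RT,11,1,2,1.89
Short RT,11,1,3,1.75
Short RT,11,2,1,2.11
Short RT,11,2,2,2.16
Short RT,11,2,3,2.12
Short RT,12,1,1,2.58
Short RT,12,1,2,2.54
Short RT,12,1,3,2.59
Short RT,12,2,1,2.77
Short RT,12,2,2,2.65
Short RT,12,2,3,2.60
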