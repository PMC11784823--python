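code,rpn_reported,rank_rpn_reported,frpn_reported,rank_frpn_reported
FM14,182.0,2,7.0,1
FM16,116.67,5,6.73,2
FM7,88.0,9,6.59,3
FM15,121.33,4,6.39,4
FM9,213.33,1,6.39,4
FM11,116.67,5,6.24,5
FM8,92.89,8,6.13,6
FM17,54.19,14,6.0,7
FM3,70.52,12,6.0,7
FM12,130.67,3,6.0,7
FM13,130.67,3,6.0,7
FM2,42.37,17,5.64,8
FM21,106.33,6,5.64,8
FM4,40.0,18,5.41,9
FM20,80.0,11,5.27,10
FM23,65.19,13,5.24,11
FM24,65.19,13,5.24,11
FM1,45.63,15,5.18,12
FM19,83.33,10,5.11,13
FM10,103.7,7,5.01,14
FM22,30.22,19,5.0,15
FM6,28.44,20,5.0,16
FM18,42.67,16,5.0,16
FM5,33.0,19,3.64,17
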