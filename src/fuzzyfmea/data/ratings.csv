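expert,code,O,S,D
1,FM1,7,2,1
1,FM2,5,4,1
1,FM3,6,5,1
1,FM4,5,4,2
1,FM5,5,3,2
1,FM6,2,5,1
1,FM7,4,6,3
1,FM8,4,6,3
1,FM9,9,8,3
1,FM10,2,9,2
1,FM11,2,9,3
1,FM12,2,10,3
1,FM13,2,10,3
1,FM14,3,10,3
1,FM15,2,9,7
1,FM16,2,9,7
1,FM17,2,5,2
1,FM18,2,5,2
1,FM19,5,10,2
1,FM20,5,10,1
1,FM21,5,10,2
1,FM22,3,5,2
1,FM23,5,10,2
1,FM24,5,10,2
2,FM1,3,3,4
2,FM2,1,2,3
2,FM3,3,5,3
2,FM4,2,2,3
2,FM5,2,1,3
2,FM6,2,1,3
2,FM7,4,5,4
2,FM8,4,5,4
2,FM9,7,5,4
2,FM10,7,5,4
2,FM11,4,5,7
2,FM12,4,10,5
2,FM13,4,10,5
2,FM14,6,10,5
2,FM15,4,10,3
2,FM16,3,10,3
2,FM17,2,7,4
2,FM18,2,5,3
2,FM19,2,8,2
2,FM20,1,9,3
2,FM21,3,10,2
2,FM22,1,5,2
2,FM23,3,5,2
2,FM24,3,5,2
3,FM1,4,6,3
3,FM2,5,7,4
3,FM3,5,7,4
3,FM4,3,6,4
3,FM5,4,5,4
3,FM6,4,6,4
3,FM7,3,7,5
3,FM8,3,8,5
3,FM9,8,7,5
3,FM10,5,6,4
3,FM11,4,7,5
3,FM12,3,8,6
3,FM13,3,8,6
3,FM14,4,7,6
3,FM15,3,7,4
3,FM16,4,6,4
3,FM17,3,7,5
3,FM18,4,6,4
3,FM19,3,7,5
3,FM20,2,8,6
3,FM21,3,9,5
3,FM22,2,7,4
3,FM23,2,7,4
3,FM24,2,7,4
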