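id,label,alpha,beta1,beta2
1,Wish to live,2.366,0.029,0.556
2,Wish to die,3.197,-0.159,0.180
3,Reasons living/dying,3.036,0.034,0.937
4,Desire to kill oneself,4.082,-0.123,0.691
5,Passive suicidal desire,2.270,-0.188,0.898
6,Duration of suicide ideation,3.434,0.276,1.054
7,Frequency of thinking about suicide,4.117,0.171,1.243
8,Acceptance of idea of suicide,3.437,0.071,0.985
9,Control over suicide action,3.165,0.386,1.587
10,Reasons for not committing suicide,3.048,0.263,1.258
11,Reasons for wanting to commit suicide,1.557,0.001,0.100
12,Specific plan to commit suicide,3.003,0.305,1.122
13,Access to suicide method,2.479,0.550,0.616
14,Courage and ability to commit suicide,3.780,0.045,0.932
15,Expectation to commit suicide,3.825,0.232,1.369
16,Preparations for suicide,2.532,0.754,1.815
17,Writing of suicide note,1.786,1.016,1.952
18,Final acts in anticipation of death,1.098,0.887,2.414
19,"Hide, conceal, or lie about suicide ideation",1.436,0.334,1.466
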