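state,reported_2005,map_2003
Alabama,1750000,1313020
Delaware,45000,38880
Georgia,1470000,1191410
Kansas,400000,637370
Kentucky,847911,518650
Louisiana,750000,1273790
Maine,213000,209420
Maryland,276000,211590
Massachusetts,90000,77390
Minnesota,1104800,759990
Mississippi,1700000,1767950
Missouri,1600000,1071110
Nebraska,200000,597830
New Hampshire,93417,92070
New Jersey,161509,129420
New York,940000,554740
North Carolina,1111000,1285590
Oklahoma,425000,1014740
Rhode Island,13000,15990
South Carolina,800000,807740
Texas,3367200,3385920
Vermont,123000,111630
Virginia,1000000,682330
West Virginia,761000,561530
Wisconsin,1112300,2119670
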