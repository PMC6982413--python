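state,est_2001_02,est_2002_03,est_2003_04,est_2004_05,map_2003,qdma_2005
Alabama,1750000,1750000,1750000,1750000,1313020,1750000
Arkansas,1000000,1000000,750000,750000,686810,
Florida,,800000,800000,800000,525210,
Georgia,1200000,1200000,1200000,1100000,1191410,1470000
Kentucky,850000,850000,900000,900000,518650,847911
Louisiana,1000000,1000000,1000000,1000000,1273790,750000
Maryland,240000,296000,264000,242000,211590,276000
Mississippi,1500000,1500000,1625000,1625000,1767950,1700000
Missouri,,1000000,1000000,1000000,1071110,1600000
North Carolina,1100000,1000000,1080000,1111000,1285590,1111000
Oklahoma,475000,475000,500000,500000,1014740,425000
South Carolina,1000000,1000000,900000,800000,807740,800000
Tennessee,999000,990000,990000,881500,736820,
Texas,3776052,3826146,4007748,3915862,3385920,3367200
Virginia,900000,970000,1000000,950000,682330,1000000
West Virginia,940000,965000,848000,901000,561530,761000
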