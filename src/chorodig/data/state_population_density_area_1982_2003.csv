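state,population_1982,density_1982,area_1982,population_2003,density_2003,area_2003
Alabama,960480,7.2,133410,1313020,9.8,133720
Arizona,107170,0.4,57930,87110,0.3,47090
Arkansas,680320,4.9,137670,686810,5.0,137720
California,0,0.0,0,180,0.0,100
Colorado,37750,0.1,20410,272440,1.0,118400
Connecticut,23920,1.8,12840,73340,5.7,12900
Delaware,9470,1.8,5110,38880,7.4,5250
Florida,444180,2.9,130900,525210,3.5,147510
Georgia,720390,4.7,151590,1191410,7.8,152390
Idaho,111610,0.5,60330,789900,3.6,171590
Illinois,275790,1.9,145780,537490,3.7,145910
Indiana,246460,2.6,93670,627170,6.7,93700
Iowa,270110,1.9,145740,353060,2.4,145740
Kansas,367210,1.7,198490,637370,3.0,213100
Kentucky,320540,3.1,104660,518650,5.0,104660
Louisiana,424450,3.5,94390,1273790,10.4,121160
Maine,185920,2.2,81880,209420,2.4,83940
Maryland,72430,2.7,25510,211590,7.9,22830
Massachusetts,42670,2.0,19610,77390,3.6,20440
Michigan,812250,5.4,146750,1250570,8.3,149700
Minnesota,683410,3.1,214220,759990,3.5,218500
Mississippi,803860,6.5,123270,1767950,14.3,123470
Missouri,378350,2.1,180550,1071110,5.9,180550
Montana,289870,0.8,156620,763120,2.0,281270
Nebraska,335290,1.7,165220,597830,3.0,200340
Nevada,0,0.0,0,270,0.0,150
New Hampshire,44350,1.8,23950,92070,3.8,23910
New Jersey,104950,5.2,17840,129420,6.4,19880
New Mexico,61760,0.2,33390,96890,0.3,52370
New York,749340,5.9,123810,554740,4.4,126570
North Carolina,737340,5.7,119680,1285590,9.9,127870
North Dakota,350370,1.9,182230,338820,1.9,183100
Ohio,200410,1.9,106610,547460,5.1,106960
Oklahoma,328280,1.8,175180,1014740,5.6,181030
Oregon,14570,0.1,6660,76840,0.3,33030
Pennsylvania,663490,5.7,116420,798120,6.8,117320
Rhode Island,8590,3.0,2090,15990,5.6,2550
South Carolina,406640,5.0,77820,807740,10.0,80400
South Dakota,410140,2.1,199720,369770,1.9,199730
Tennessee,285840,2.6,109140,736820,6.8,109160
Texas,2219730,3.2,345460,3385920,4.9,586980
Utah,0,0.0,0,30,0.0,20
Vermont,78570,3.2,24090,111630,4.5,24820
Virginia,390180,3.7,102110,682330,6.5,103320
Washington,62510,0.4,33790,126860,0.7,67970
West Virginia,405070,6.5,62760,561530,8.9,62760
Wisconsin,730900,5.0,143970,2119670,14.6,145180
Wyoming,289800,1.1,139050,440690,1.7,174630
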