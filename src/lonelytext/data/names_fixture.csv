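name,gender,count
alice,F,14231
emma,F,19800
olivia,F,18420
sophia,F,17210
isabella,F,15030
mia,F,12990
charlotte,F,12010
amelia,F,11840
harper,F,9950
evelyn,F,9020
abigail,F,8830
emily,F,8710
elizabeth,F,8420
sofia,F,8100
avery,F,7950
ella,F,7800
scarlett,F,7420
grace,F,7300
chloe,F,7150
victoria,F,7000
aria,F,6900
lily,F,6820
aubrey,F,6600
zoey,F,6410
penelope,F,6300
layla,F,6150
nora,F,6000
hannah,F,5900
yelena,F,410
anya,F,980
margaret,F,5400
james,M,20100
john,M,19850
robert,M,19500
michael,M,19310
william,M,18970
david,M,18400
richard,M,15200
joseph,M,14800
thomas,M,14100
charles,M,13800
christopher,M,13200
daniel,M,12900
matthew,M,12400
anthony,M,11800
donald,M,11300
mark,M,10900
paul,M,10500
steven,M,10100
andrew,M,9800
kenneth,M,9300
joshua,M,9000
kevin,M,8700
brian,M,8400
george,M,8100
edward,M,7800
ronald,M,7500
timothy,M,7200
jason,M,6900
jeffrey,M,6600
ryan,M,6300
jordan,F,2100
jordan,M,5200
taylor,F,4100
taylor,M,2900
casey,F,1800
casey,M,2200
morgan,F,3300
morgan,M,1400
riley,F,2600
riley,M,1900
jamie,F,2300
jamie,M,2700
alexis,F,3900
alexis,M,900
skyler,F,800
skyler,M,700
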