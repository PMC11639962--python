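activity_rank,japanese_name,scientific_name,ec50_ug_ml,viability_pct,sample_id
1,コフキサルノコシカケ (購入),Elfvingia applanata (purchased),6.21,40.5,t208
2,コツブタケ,Pisolithus tinctorius,7.15,55.4,t132
3,キコブタケ,Phellinus igniarius,7.54,45.8,t035
4,カバノアナタケ,Fuscoporia obliqua,7.94,60.0,t100
5,サジタケ,Onnia scaura,10.4,36.5,t039
6,ハナガサタケ,Pholiota flammans,15.8,50.2,t044
7,ツリガネタケ,Fomes fomentarius,17.2,36.9,t034
8,コフキサルノコシカケ,Elfvingia applanata,18.1,49.6,t037
9,オシロイタケ,Oligoporus tephroleucus,19.2,50.5,t145
10,クロカワ,Boletopsis leucomelas,37.5,65.3,t020
11,ヌメリスギタケモドキ,Pholiota aurivella,47.7,43.4,t048
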