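mutant,target,ki_pm,sd_pm
parent,mesotrypsin,98.0,1.0
parent,anionic_trypsin,2.26,0.08
parent,cationic_trypsin,22.5,0.6
parent,KLK6,362,10
T11V/G17R,mesotrypsin,494,28
T11V/G17R,anionic_trypsin,0.92,0.07
T11V/G17R,cationic_trypsin,2.37,0.17
T11V/G17R,KLK6,16.4,0.9
T11S/G17R,mesotrypsin,1060,30
T11S/G17R,anionic_trypsin,2.98,0.19
T11S/G17R,cationic_trypsin,7.25,0.5
T11S/G17R,KLK6,124,13
T11S,mesotrypsin,581,7
T11S,anionic_trypsin,1.16,0.09
T11S,cationic_trypsin,7.63,0.55
T11S,KLK6,1000,60
T11V,mesotrypsin,65.0,1.0
T11V,anionic_trypsin,3.72,0.21
T11V,cationic_trypsin,14.1,0.5
T11V,KLK6,378,9
G17R,mesotrypsin,676,8
G17R,anionic_trypsin,3.58,0.16
G17R,cationic_trypsin,8.12,0.08
G17R,KLK6,77.4,2.6
T11H,mesotrypsin,302,24
T11H,anionic_trypsin,4.45,0.23
T11I,mesotrypsin,61.2,2.6
T11I,anionic_trypsin,1.44,0.14
G17E,KLK6,464,39
G17E,cationic_trypsin,85.8,5.9
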