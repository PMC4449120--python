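# Approximate province-centroid coordinates for the 14 living Koreanic
# variant sample locations (synthetic stand-in: hand-placed centroids,
# not the coordinates used by any published analysis).
id,lon,lat
Jeju_1,126.55,33.38
SJeolla_2,126.90,34.85
NJeolla_3,127.15,35.70
SGyeongsang_4,128.25,35.25
NGyeongsang_5,128.70,36.35
SChungcheong_6,126.80,36.50
NChungcheong_7,127.70,36.75
Gyeonggi_8,127.05,37.40
Gangwon_9,128.20,37.75
Hwanghae_10,125.75,38.40
SPyongan_11,125.85,39.20
NPyongan_12,125.40,40.00
SHamgyong_13,127.50,40.05
NHamgyong_14,129.20,41.50
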