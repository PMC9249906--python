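code,role,label
0,other,no data
10,cropland,cropland rainfed
20,cropland,cropland irrigated or post-flooding
30,mosaic_cropland,mosaic cropland (>50%) / natural vegetation (<50%)
40,mosaic_cropland,mosaic natural vegetation (>50%) / cropland (<50%)
50,other,tree cover broadleaved evergreen
60,other,tree cover broadleaved deciduous
70,other,tree cover needleleaved evergreen
80,other,tree cover needleleaved deciduous
90,other,tree cover mixed leaf type
100,other,mosaic tree and shrub (>50%) / herbaceous cover (<50%)
110,herbaceous_mosaic,mosaic herbaceous cover (>50%) / tree and shrub (<50%)
120,shrubland,shrubland
130,grassland,grassland
140,other,lichens and mosses
150,sparse,sparse vegetation (tree shrub herbaceous cover <15%)
160,other,tree cover flooded fresh or brackish water
170,other,tree cover flooded saline water
180,other,shrub or herbaceous cover flooded
190,other,urban areas
200,bare,bare areas
210,other,water bodies
220,other,permanent snow and ice
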