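# 24-patch colour chart (ColorChecker-style), CIE L*a*b* under D65 / 2 deg observer.
# Provenance: computed from the chart's widely published nominal sRGB coordinates
# (the de-facto standard 8-bit sRGB values for the 24 patches) via the standard
# IEC 61966-2-1 sRGB -> XYZ -> CIELAB conversion, using scikit-image 0.26 as an
# independent reference implementation; values frozen here to 0.01.
# The grayscale wedge (patches 19-24) is idealised to exact neutrality
# (a* = b* = 0, i.e. r = g = b nominal codes), matching the chart's
# spectrally flat grayscale design.
# Layout: row-major, 4 rows x 6 columns; the neutral (grayscale) row is last,
# white first in that row, black last.
index,name,L,a,b
1,dark_skin,38.02,11.80,13.67
2,light_skin,65.67,13.67,16.90
3,blue_sky,50.63,0.37,-21.60
4,foliage,43.00,-15.88,20.45
5,blue_flower,55.68,12.76,-25.17
6,bluish_green,70.99,-30.64,1.54
7,orange,61.14,28.10,56.13
8,purplish_blue,41.12,17.41,-41.88
9,moderate_red,51.33,42.10,14.89
10,purple,31.10,24.35,-22.10
11,yellow_green,71.90,-28.10,56.96
12,orange_yellow,71.04,12.60,64.92
13,blue,30.35,26.43,-49.67
14,green,55.03,-40.14,32.30
15,red,41.35,49.30,24.66
16,yellow,80.70,-3.66,77.55
17,magenta,51.14,48.15,-15.28
18,cyan,51.15,-19.73,-23.37
19,white,95.84,0.00,0.00
20,neutral_8,80.60,0.00,0.00
21,neutral_6_5,65.87,0.00,0.00
22,neutral_5,51.22,0.00,0.00
23,neutral_3_5,36.15,0.00,0.00
24,black,21.70,0.00,0.00
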