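"""Embedded connection tables for the bundled reference molecules.

Each entry is a kekulized MDL V2000 record identified by compound name.
Structures were encoded once from their literature connectivity; the
registry is frozen and guarded by a checksum test.
"""

SDF_BLOCKS = {
    'afatinib': '''\
afatinib
     RDKit          2D

 34 37  0  0  0  0  0  0  0  0999 V2000
   -9.0905   -4.3611    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -8.1449   -3.1967    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -8.6805   -1.7956    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.6637   -3.4333    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.7181   -2.2689    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2369   -2.5056    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2913   -1.3411    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.8270    0.0600    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8101   -1.5778    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8646   -0.4133    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6166   -0.6500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5622    0.5144    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0434    0.2778    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5791   -1.1233    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    5.0603   -1.3600    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.5959   -2.7611    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.0771   -2.9978    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    8.0227   -1.8333    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    9.5039   -2.0700    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
    7.4871   -0.4322    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    8.4326    0.7322    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    6.0058   -0.1956    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.9890    1.4422    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    3.4533    2.8433    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9721    3.0800    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    1.0265    1.9155    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4547    2.1522    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4002    0.9878    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8814    1.2244    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.4171    2.6255    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.8654    3.0157    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.9419    4.5138    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5408    5.0494    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5984    3.8824    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  7  9  1  0
  9 10  1  0
 10 11  2  0
 11 12  1  0
 12 13  2  0
 13 14  1  0
 14 15  1  0
 15 16  2  0
 16 17  1  0
 17 18  2  0
 18 19  1  0
 18 20  1  0
 20 21  1  0
 20 22  2  0
 13 23  1  0
 23 24  2  0
 24 25  1  0
 25 26  2  0
 26 27  1  0
 27 28  2  0
 28 29  1  0
 29 30  1  0
 30 31  1  0
 31 32  1  0
 32 33  1  0
 33 34  1  0
 28 10  1  0
 34 30  1  0
 26 12  1  0
 22 15  1  0
M  END
$$$$
''',
    'aniline': '''\
aniline
     RDKit          2D

  7  7  0  0  0  0  0  0  0  0999 V2000
    2.5714    0.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    1.0714   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3214   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1786   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9286    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1786    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3214    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  2  1  0
M  END
$$$$
''',
    'benzene': '''\
benzene
     RDKit          3D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.0734    0.8905   -0.0210 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3080   -0.4844   -0.0077 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.2346   -1.3749    0.0133 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0734   -0.8905    0.0210 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3080    0.4844    0.0077 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2346    1.3749   -0.0133 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
$$$$
''',
    'cyclohexane': '''\
cyclohexane
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  1  1  0
M  END
$$$$
''',
    'dasatinib_2d': '''\
dasatinib_2d
     RDKit          2D

 33 36  0  0  0  0  0  0  0  0999 V2000
   -7.1509    0.1536    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6734    0.4124    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1588    1.8214    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -3.6813    2.0801    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1667    3.4891    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6891    3.7479    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0301    5.0953    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.4551    4.8849    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7139    3.4074    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6113    2.7047    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
    2.0613    2.7483    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.3059    3.5856    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.1643    1.2518    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    3.5117    0.5927    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.6146   -0.9038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3701   -1.7411    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.9621   -1.5628    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.2066   -0.7255    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.1037    0.7710    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.7562    1.4301    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6533    2.9265    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -2.7184    0.9300    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2331   -0.4790    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.7106   -0.7378    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2702   -1.6291    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7848   -3.0381    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8220   -4.1883    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3445   -3.9295    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.6184   -5.0796    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.1038   -6.4886    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0667   -7.6388    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.1702   -2.5205    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7927   -1.3704    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9 10  1  0
  9 11  1  0
 11 12  2  0
 11 13  1  0
 13 14  1  0
 14 15  2  0
 15 16  1  0
 15 17  1  0
 17 18  2  0
 18 19  1  0
 19 20  2  0
 20 21  1  0
  4 22  2  0
 22 23  1  0
 23 24  2  0
 23 25  1  0
 25 26  1  0
 26 27  1  0
 27 28  1  0
 28 29  1  0
 29 30  1  0
 30 31  1  0
 28 32  1  0
 32 33  1  0
 24  2  1  0
 33 25  1  0
 10  6  1  0
 20 14  1  0
M  END
$$$$
''',
    'dasatinib_3d': '''\
dasatinib
     RDKit          3D

 33 36  0  0  0  0  0  0  0  0999 V2000
    1.7547    2.4125    3.0324 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.7558    1.5399    1.8173 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5697    1.2335    1.2752 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.5745    0.5002    0.1552 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6280    0.1571   -0.5014 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8244    0.7416   -0.2559 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0411    1.9838    0.1138 N   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3930    2.2260    0.2431 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2245    1.1684   -0.0589 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2681   -0.1774   -0.5162 S   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6776    1.1549   -0.0159 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.3097    2.1572    0.3004 O   0  0  0  0  0  0  0  0  0  0  0  0
   -6.2538   -0.0376   -0.4169 N   0  0  0  0  0  0  0  0  0  0  0  0
   -7.6310   -0.3500   -0.5456 C   0  0  0  0  0  0  0  0  0  0  0  0
   -8.6531    0.1088    0.3081 C   0  0  0  0  0  0  0  0  0  0  0  0
   -8.4318    0.9082    1.5639 C   0  0  0  0  0  0  0  0  0  0  0  0
   -9.9908   -0.2340    0.0143 C   0  0  0  0  0  0  0  0  0  0  0  0
  -10.3148   -1.0651   -1.0575 C   0  0  0  0  0  0  0  0  0  0  0  0
   -9.3029   -1.5821   -1.8551 C   0  0  0  0  0  0  0  0  0  0  0  0
   -7.9762   -1.2344   -1.5957 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.7567   -1.9024   -2.6367 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    1.7626    0.0617   -0.4046 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.9511    0.3984    0.2207 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.9465    1.1548    1.3287 N   0  0  0  0  0  0  0  0  0  0  0  0
    4.1759   -0.0162   -0.3459 N   0  0  0  0  0  0  0  0  0  0  0  0
    5.3486    0.6279    0.2855 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.6477    0.2187   -0.4500 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.8414   -1.2507   -0.5095 N   0  0  0  0  0  0  0  0  0  0  0  0
    8.0401   -1.6193   -1.2810 C   0  0  0  0  0  0  0  0  0  0  0  0
    9.3660   -1.2567   -0.5946 C   0  0  0  0  0  0  0  0  0  0  0  0
   10.4684   -1.7138   -1.3770 O   0  0  0  0  0  0  0  0  0  0  0  0
    5.6381   -1.8667   -1.1174 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.3245   -1.4861   -0.3934 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9 10  1  0
  9 11  1  0
 11 12  2  0
 11 13  1  0
 13 14  1  0
 14 15  2  0
 15 16  1  0
 15 17  1  0
 17 18  2  0
 18 19  1  0
 19 20  2  0
 20 21  1  0
  4 22  2  0
 22 23  1  0
 23 24  2  0
 23 25  1  0
 25 26  1  0
 26 27  1  0
 27 28  1  0
 28 29  1  0
 29 30  1  0
 30 31  1  0
 28 32  1  0
 32 33  1  0
 24  2  1  0
 33 25  1  0
 10  6  1  0
 20 14  1  0
M  END
$$$$
''',
    'ethanol': '''\
ethanol
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
   -1.2990   -0.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990   -0.2500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
''',
    'ethylbenzene': '''\
ethylbenzene
     RDKit          2D

  8  8  0  0  0  0  0  0  0  0999 V2000
   -3.0851    0.4695    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0677   -0.6327    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6045   -0.3028    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1586    1.1294    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3047    1.4594    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3221    0.3572    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8762   -1.0750    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.4129   -1.4050    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  3  1  0
M  END
$$$$
''',
    'gefitinib': '''\
gefitinib
     RDKit          2D

 31 34  0  0  0  0  0  0  0  0999 V2000
   -3.1203   -4.5157    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7002   -4.9987    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5719   -4.0104    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8483   -4.4934    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9766   -3.5051    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.3967   -3.9881    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    4.5251   -2.9998    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.2333   -1.5284    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.8132   -1.0454    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5215    0.4260    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    3.6498    1.4143    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0699    0.9313    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.1983    1.9196    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.9065    3.3910    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.0349    4.3793    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
    4.4864    3.8740    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.1947    5.3454    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    3.3581    2.8857    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.6849   -2.0337    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.2648   -1.5507    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8636   -2.5390    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2837   -2.0560    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5754   -0.5847    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.9956   -0.1016    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2873    1.3697    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.7074    1.8527    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9991    3.3241    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -7.4193    3.8071    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -8.5476    2.8188    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -8.2559    1.3474    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.8358    0.8644    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  9  1  0
  9 10  1  0
 10 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  2  0
 14 15  1  0
 14 16  1  0
 16 17  1  0
 16 18  2  0
  9 19  2  0
 19 20  1  0
 20 21  2  0
 21 22  1  0
 22 23  1  0
 23 24  1  0
 24 25  1  0
 25 26  1  0
 26 27  1  0
 27 28  1  0
 28 29  1  0
 29 30  1  0
 30 31  1  0
 21  3  1  0
 31 26  1  0
 19  5  1  0
 18 11  1  0
M  END
$$$$
''',
    'methane': '''\
methane
     RDKit          2D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
''',
    'naphthalene': '''\
naphthalene
     RDKit          2D

 10 11  0  0  0  0  0  0  0  0999 V2000
   -2.5981   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5981    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2990    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0000    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990   -1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2990   -1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  9  1  0
  9 10  2  0
 10  1  1  0
  9  4  1  0
M  END
$$$$
''',
    'osimertinib': '''\
osimertinib
     RDKit          3D

 37 40  0  0  0  0  0  0  0  0999 V2000
   -1.2407    3.4746   -3.9154 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8554    2.9037   -2.7674 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4010    1.5761   -2.3487 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2089    0.9871   -3.0536 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8024    1.1474   -1.1802 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1370   -0.0069   -0.4273 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0610   -0.6207    0.2382 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2225   -1.7882    0.9901 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8396   -2.4395    1.6396 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.2206   -2.3048    1.6085 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.9049   -3.1549    2.3923 N   0  0  0  0  0  0  0  0  0  0  0  0
    4.2475   -3.0686    2.3736 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.9394   -2.1694    1.6044 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.1616   -1.3394    0.8334 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.7574   -0.3629   -0.0663 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.2600   -0.1366   -1.3364 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0447    0.8017   -1.9466 N   0  0  0  0  0  0  0  0  0  0  0  0
    4.8520    1.2803   -3.2971 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0428    1.2193   -1.0919 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.0684    2.1622   -1.2702 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.9431    2.3940   -0.2059 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.7994    1.7125    0.9977 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.7759    0.7734    1.1660 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.8820    0.5079    0.1041 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.8146   -1.3965    0.8254 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5144   -2.3399    1.0891 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6042   -3.4830    1.8529 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8666   -4.1371    1.8887 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5976   -1.7115    0.4628 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4413   -0.5271   -0.2848 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5691    0.1511   -0.7574 N   0  0  0  0  0  0  0  0  0  0  0  0
   -4.5937   -0.6225   -1.4430 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.9931    1.3352    0.0039 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.6753    1.0211    1.3612 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9785    0.3165    1.3050 N   0  0  0  0  0  0  0  0  0  0  0  0
   -6.3754   -0.1089    2.6486 C   0  0  0  0  0  0  0  0  0  0  0  0
   -7.0233    1.1566    0.7182 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  3  5  1  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  1  0
  9 10  1  0
 10 11  2  0
 11 12  1  0
 12 13  2  0
 13 14  1  0
 14 15  1  0
 15 16  2  0
 16 17  1  0
 17 18  1  0
 17 19  1  0
 19 20  2  0
 20 21  1  0
 21 22  2  0
 22 23  1  0
 23 24  2  0
 14 25  2  0
  8 26  2  0
 26 27  1  0
 27 28  1  0
 26 29  1  0
 29 30  2  0
 30 31  1  0
 31 32  1  0
 31 33  1  0
 33 34  1  0
 34 35  1  0
 35 36  1  0
 35 37  1  0
 30  6  1  0
 25 10  1  0
 24 15  1  0
 24 19  1  0
M  END
$$$$
''',
    'piperazine': '''\
piperazine
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  1  1  0
M  END
$$$$
''',
    'propane': '''\
propane
     RDKit          2D

  3  2  0  0  0  0  0  0  0  0999 V2000
   -1.2990   -0.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2990   -0.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
''',
    'pyridine': '''\
pyridine
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
$$$$
''',
    'pyrrole': '''\
pyrrole
     RDKit          2D

  5  5  0  0  0  0  0  0  0  0999 V2000
    1.2760   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943    1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323   -0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943   -1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  1  0
  5  1  2  0
M  END
$$$$
''',
    'stereo_R': '''\
stereo_R
     RDKit          3D

  4  3  0  0  0  0  0  0  0  0999 V2000
   -0.0576   -0.1051   -0.0841 C   0  0  1  0  0  0  0  0  0  0  0  0
   -0.3388   -1.2118    0.6487 F   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2451    1.1540    0.2505 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    1.7251    0.5278    0.3302 Br  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  1
  1  3  1  0
  1  4  1  0
M  END
$$$$
''',
    'stereo_S': '''\
stereo_S
     RDKit          3D

  4  3  0  0  0  0  0  0  0  0999 V2000
   -0.0570   -0.1138    0.0724 C   0  0  2  0  0  0  0  0  0  0  0  0
   -0.3057   -1.1476   -0.7704 F   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2618    1.1521   -0.1590 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    1.7204    0.5864   -0.2452 Br  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  6
  1  3  1  0
  1  4  1  0
M  END
$$$$
''',
    'toluene': '''\
toluene
     RDKit          2D

  7  7  0  0  0  0  0  0  0  0999 V2000
    2.5714    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0714   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3214   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1786   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9286    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1786    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3214    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  2  1  0
M  END
$$$$
''',
    'water': '''\
water
     RDKit          2D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
''',
}
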