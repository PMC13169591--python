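0.99595811 0.08980360 0.00166285
-0.71082944 0.70156798 -0.05023819
0.00036859 -0.99878692 -0.04923976
0.70509036 0.70874242 0.02305984
-0.92176229 -0.27611294 0.27224239
0.87924181 -0.44186522 0.17801392
-0.29134009 0.94444320 0.15214465
-0.45592016 -0.88668520 0.07698154
0.91076539 0.40995585 0.04942273
-0.96375457 0.25494493 0.07861436
0.46161300 -0.87849254 0.12314344
0.27235374 0.94514496 0.18034534
-0.79820520 -0.55747582 0.22823054
0.96339912 -0.13202910 0.23330336
-0.56425972 0.79544634 0.22107936
-0.17976899 -0.96062834 0.21184026
0.77437040 0.55311562 0.30726795
-0.94971559 0.03592685 0.31104592
0.67129826 -0.65405540 0.34866917
-0.02852002 0.92636835 0.37553734
-0.56520743 -0.75068726 0.34206608
0.92554481 0.21499043 0.31168241
-0.82106095 0.54170156 0.18005090
0.17294209 -0.96082965 0.21655813
0.53552417 0.79701123 0.27926146
-0.79852487 -0.20376106 0.56642692
0.80081350 -0.34857221 0.48702685
-0.33348162 0.81889586 0.46711837
-0.29588130 -0.82949958 0.47369263
0.75486342 0.35721180 0.55007359
-0.84417928 0.34836137 0.40743798
0.39013966 -0.80931740 0.43908586
0.26244565 0.83068944 0.49099627
-0.69453328 -0.49359276 0.52344026
0.85821134 -0.03553678 0.51206487
-0.62613385 0.62022506 0.47252225
0.03153739 -0.87485663 0.48335419
0.53896926 0.63405453 0.55451510
-0.79709824 0.09947409 0.59559995
0.56991335 -0.54946551 0.61097170
-0.05669986 0.75567290 0.65249031
-0.43909138 -0.60338878 0.66567315
0.68892157 0.10152482 0.71769059
-0.63380300 0.37663141 0.67560531
0.22004707 -0.69971993 0.67968471
0.23697196 0.63436783 0.73581366
-0.55924700 -0.29108032 0.77621842
0.62558769 -0.21764843 0.74917902
-0.37131179 0.60451636 0.70476062
-0.12074019 -0.68336970 0.72001921
0.49678687 0.40378412 0.76821949
-0.58506902 0.03713909 0.81013266
0.37670868 -0.45047893 0.80941912
-0.09654761 0.50670945 0.85669370
-0.27095221 -0.40768599 0.87199601
0.44384981 0.10355922 0.89009709
-0.39640380 0.30796623 0.86488197
0.06173100 -0.46847293 0.88131856
0.19343490 0.37482889 0.90668972
-0.32982166 -0.07496430 0.94106218
0.31714814 -0.18712949 0.92973093
-0.13932337 0.19294462 0.97126792
-0.03602760 -0.18669271 0.98175753
0.13926391 0.07608473 0.98732805
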