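MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF Arid3
letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
0.815406 0.013991 0.018120 0.152483
0.015998 0.024064 0.044228 0.915710
0.023033 0.015721 0.000815 0.960431
0.877051 0.046075 0.022076 0.054798
0.906611 0.001615 0.082881 0.008892
0.000825 0.024070 0.158527 0.816578

MOTIF CEBPB
letter-probability matrix: alength= 4 w= 11 nsites= 20 E= 0
0.780905 0.051538 0.051839 0.115719
0.004708 0.001728 0.102161 0.891402
0.035263 0.017958 0.055572 0.891206
0.028488 0.025617 0.936818 0.009077
0.006444 0.949442 0.002678 0.041436
0.016632 0.015838 0.941459 0.026070
0.006464 0.929715 0.010970 0.052851
0.931287 0.050837 0.009934 0.007942
0.932956 0.000252 0.033484 0.033308
0.076027 0.135871 0.038482 0.749620
0.252211 0.498090 0.242645 0.007054

MOTIF FOSL1
letter-probability matrix: alength= 4 w= 11 nsites= 20 E= 0
0.144326 0.058045 0.539378 0.258251
0.059528 0.028484 0.023170 0.888818
0.105455 0.012795 0.867693 0.014057
0.904898 0.009378 0.022245 0.063479
0.006111 0.898989 0.069010 0.025889
0.046825 0.041151 0.002665 0.909358
0.002457 0.936897 0.041031 0.019616
0.930890 0.032251 0.034434 0.002425
0.211937 0.061166 0.022024 0.704872
0.025921 0.535991 0.178179 0.259910
0.525708 0.000731 0.465412 0.008149

MOTIF Gabpa
letter-probability matrix: alength= 4 w= 11 nsites= 20 E= 0
0.722329 0.045614 0.004017 0.228039
0.090964 0.860879 0.046038 0.002119
0.023858 0.918657 0.056961 0.000524
0.005996 0.001882 0.962945 0.029177
0.006193 0.001419 0.938146 0.054241
0.864135 0.072698 0.043447 0.019720
0.932073 0.045238 0.003274 0.019415
0.031615 0.037855 0.915331 0.015199
0.051123 0.208590 0.025465 0.714821
0.012833 0.011931 0.571864 0.403372
0.003095 0.330557 0.524187 0.142162

MOTIF MEF2A
letter-probability matrix: alength= 4 w= 15 nsites= 20 E= 0
0.520905 0.076696 0.272566 0.129833
0.396103 0.033128 0.502303 0.068465
0.056686 0.694761 0.119117 0.129436
0.013084 0.069970 0.001175 0.915771
0.966271 0.012153 0.004507 0.017068
0.011661 0.030600 0.206576 0.751163
0.035180 0.024941 0.140312 0.799567
0.058157 0.045177 0.094698 0.801968
0.058601 0.116270 0.020923 0.804206
0.021869 0.032206 0.006796 0.939129
0.899257 0.050527 0.039972 0.010245
0.004502 0.149204 0.792183 0.054111
0.125418 0.585045 0.221399 0.068137
0.439895 0.019382 0.033850 0.506872
0.026955 0.358161 0.516851 0.098033

MOTIF MAFK
letter-probability matrix: alength= 4 w= 15 nsites= 20 E= 0
0.036933 0.069748 0.484873 0.408445
0.164120 0.025840 0.025050 0.784990
0.007874 0.039191 0.901924 0.051010
0.004226 0.908048 0.004863 0.082863
0.059274 0.046042 0.001387 0.893296
0.061678 0.003561 0.875750 0.059012
0.947934 0.022342 0.009707 0.020016
0.049761 0.905235 0.021471 0.023534
0.030817 0.004432 0.911737 0.053014
0.087452 0.016302 0.014121 0.882125
0.019350 0.930239 0.030298 0.020113
0.869417 0.117850 0.004774 0.007959
0.039746 0.046344 0.708011 0.205899
0.014041 0.784709 0.132629 0.068620
0.607798 0.082198 0.022579 0.287425

MOTIF MAX
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
0.595094 0.043481 0.322348 0.039076
0.022139 0.740437 0.234954 0.002471
0.009054 0.895611 0.054607 0.040728
0.922442 0.017080 0.023855 0.036623
0.039367 0.917966 0.001129 0.041539
0.013841 0.083079 0.895586 0.007495
0.006133 0.049557 0.012427 0.931883
0.048458 0.062897 0.860424 0.028221
0.018005 0.080970 0.758858 0.142167
0.241193 0.032810 0.234937 0.491060

MOTIF NFYB
letter-probability matrix: alength= 4 w= 16 nsites= 20 E= 0
0.145051 0.142229 0.145957 0.566763
0.712193 0.171876 0.102091 0.013840
0.058141 0.088434 0.769024 0.084401
0.047813 0.896634 0.024692 0.030861
0.064008 0.906865 0.025957 0.003169
0.947125 0.000139 0.006852 0.045883
0.886008 0.051531 0.032636 0.029826
0.018733 0.016693 0.009670 0.954904
0.026677 0.781313 0.010784 0.181226
0.800350 0.160999 0.005337 0.033313
0.053020 0.032154 0.777489 0.137337
0.687246 0.023111 0.117847 0.171796
0.098243 0.087220 0.742649 0.071888
0.191153 0.000282 0.013003 0.795562
0.083853 0.085629 0.601293 0.229224
0.279609 0.193526 0.522403 0.004462

MOTIF SP1
letter-probability matrix: alength= 4 w= 11 nsites= 20 E= 0
0.232317 0.045932 0.687830 0.033922
0.001863 0.039535 0.956079 0.002523
0.017478 0.068150 0.906344 0.008028
0.021270 0.026705 0.936408 0.015617
0.162280 0.021666 0.784267 0.031788
0.037073 0.910935 0.045149 0.006843
0.042045 0.026595 0.905993 0.025367
0.012307 0.020747 0.882059 0.084887
0.072995 0.015035 0.896338 0.015633
0.039514 0.060746 0.782838 0.116902
0.281736 0.551811 0.086447 0.080006

MOTIF SRF
letter-probability matrix: alength= 4 w= 16 nsites= 20 E= 0
0.091642 0.120941 0.527727 0.259691
0.436564 0.000385 0.104374 0.458676
0.007689 0.951002 0.032687 0.008622
0.084259 0.879400 0.032776 0.003565
0.723123 0.050813 0.043742 0.182323
0.049374 0.112725 0.028477 0.809423
0.799185 0.140741 0.037907 0.022167
0.105830 0.002950 0.077993 0.813227
0.687029 0.055458 0.072653 0.184860
0.004661 0.097981 0.137631 0.759727
0.056542 0.002218 0.932378 0.008862
0.009400 0.004550 0.891493 0.094558
0.080404 0.018823 0.298337 0.602436
0.051133 0.484955 0.259019 0.204893
0.560265 0.034266 0.394775 0.010695
0.010180 0.157475 0.486789 0.345556

MOTIF STAT1
letter-probability matrix: alength= 4 w= 11 nsites= 20 E= 0
0.037304 0.083404 0.101959 0.777332
0.094566 0.021692 0.001470 0.882272
0.005448 0.001417 0.039343 0.953791
0.013930 0.874133 0.013609 0.098328
0.001770 0.926394 0.016955 0.054881
0.054438 0.707836 0.169290 0.068436
0.083225 0.000949 0.907865 0.007961
0.001162 0.104027 0.863563 0.031247
0.910930 0.065880 0.010803 0.012386
0.903504 0.002582 0.013751 0.080164
0.812038 0.096188 0.031804 0.059970

MOTIF YY1
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
0.009598 0.593509 0.008720 0.388172
0.812694 0.031090 0.008361 0.147855
0.753389 0.039070 0.119714 0.087827
0.005848 0.013975 0.968145 0.012032
0.920387 0.031973 0.040202 0.007438
0.049493 0.004653 0.031839 0.914015
0.027152 0.083125 0.861239 0.028484
0.000661 0.002739 0.927831 0.068769
0.001552 0.954671 0.036454 0.007322
0.202951 0.031214 0.689357 0.076478
0.012473 0.005473 0.814912 0.167141
0.086730 0.596426 0.218787 0.098057

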