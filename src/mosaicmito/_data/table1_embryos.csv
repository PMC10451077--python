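embryo_id,culturability,pre_karyotype,post_karyotype,pre_copies,post_copies,pre_counts,post_counts,printed_mean_pre,printed_mean_post
1,culturable,euploid,euploid,372395,75797,0;0;0,0,0.0,0.0
2,culturable,euploid,euploid,75232,95808,0;0,0,0.0,0.0
3,non_culturable,mosaic,euploid,ND,17865,ND;ND,1,ND,1.0
4,non_culturable,mosaic,euploid,13624,238537,0;0;0,0;0,0.0,0.0
5,non_culturable,mosaic,euploid,539604,88898,2;2;2,2,2.0,2.0
6,culturable,mosaic,euploid,131788,35764,0;0;0,0;0;0,0.0,0.0
7,culturable,mosaic,euploid,124033,94948,0;0;0,0,0.0,0.0
8,culturable,mosaic,euploid,130601,71609,0;0;0,0,0.0,0.0
9,culturable,mosaic,euploid,190039,118527,0;0,0,0.0,0.0
10,culturable,mosaic,euploid,57763,42677,1;1,1;1;1,1.0,1.0
11,culturable,mosaic,euploid,92608,105571,0;0,0,0.0,0.0
12,culturable,mosaic,euploid,ND,70918,1;0,1,0.5,1.0
13,culturable,mosaic,euploid,ND,96140,0,0,0.0,0.0
14,culturable,mosaic,euploid,ND,196321,0,0,0.0,0.0
15,culturable,euploid,mosaic,181405,38109,1,1,1.0,1.0
16,culturable,euploid,mosaic,132612,47408,1,1,1.0,1.0
17,non_culturable,mosaic,mosaic,ND,ND,ND,ND,ND,ND
18,non_culturable,mosaic,mosaic,ND,ND,0;1;0,0,0.3,0.0
19,non_culturable,mosaic,mosaic,ND,70918,2;2,2,2.0,2.0
20,non_culturable,full_aneuploid,mosaic,ND,65167,2,2,2.0,2.0
21,non_culturable,mosaic,full_aneuploid,169696,554895,2;2;2,2,2.0,2.0
22,culturable,full_aneuploid,full_aneuploid,19496,45258,2;2,2;2,2.0,2.0
23,culturable,full_aneuploid,full_aneuploid,488790,86767,1,1,1.0,1.0
24,culturable,full_aneuploid,full_aneuploid,187153,85040,0;0,0,0.0,0.0
25,not_cultured,mosaic,ND,87217,ND,0;0,ND,0.0,0.0
26,non_culturable,mosaic,ND,252566,ND,0;0;0,ND,0.0,ND
27,culturable,full_aneuploid,ND,76855,ND,1,1,1.0,1.0
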