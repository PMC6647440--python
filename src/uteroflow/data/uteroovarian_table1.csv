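id,name,region,side,length_cm,area_np_cm2,area_p_cm2,multiplicity,parent_ids,bed_id
62,Ovarian artery I,systemic_artery,left,3,0.0154,0.03079,1,,
63,Ovarian artery II,systemic_artery,left,2,0.0079,0.015,3,62,1
64,Communicating artery,systemic_artery,left,5,0.004418,0.048105,1,62,
65,Arcuate arteries I,systemic_artery,left,12,0.0123,0.1257,4,64;76,
66,Radial/spiral arteries I,systemic_artery,left,3,0.000314,0.001963,50,65,3
67,Ascending uterine artery I,systemic_artery,left,3,0.02405,0.048105,1,80,
68,Arcuate arteries II,systemic_artery,left,12,0.0123,0.1257,4,67,
69,Radial/spiral arteries II,systemic_artery,left,3,0.000314,0.001963,50,68,4
70,Ascending uterine artery II,systemic_artery,left,3,0.02405,0.048105,1,67,
71,Arcuate arteries III,systemic_artery,left,12,0.0123,0.1257,4,70,
72,Radial/spiral arteries III,systemic_artery,left,3,0.000314,0.001963,50,71,5
73,Ascending uterine artery III,systemic_artery,left,3,0.02405,0.048105,1,70,
74,Arcuate arteries IV,systemic_artery,left,12,0.0123,0.1257,4,73,
75,Radial/spiral arteries IV,systemic_artery,left,3,0.000314,0.001963,50,74,6
76,Ascending uterine artery IV,systemic_artery,left,3,0.02405,0.048105,1,73,
77,Descending uterine artery,systemic_artery,left,3,0.000314,0.001963,1,80,
78,Arcuate arteries V,systemic_artery,left,12,0.0123,0.1257,4,77,
79,Radial/spiral arteries V,systemic_artery,left,3,0.000314,0.001963,50,78,7
80,Uterine artery,systemic_artery,left,8,0.02405,0.048105,1,,
81,Vaginal artery,systemic_artery,left,7,0.00307,0.04909,1,80,7
270,Ovarian vein I,systemic_vein,left,3,0.0767,0.7854,1,271;272,
271,Ovarian vein II,systemic_vein,left,2,0.0123,0.0491,3,bed:1,
272,Communicating vein,systemic_vein,left,5,0.0767,0.7854,1,273,
273,Arcuate veins I,systemic_vein,left,12,0.0192,0.1963,4,274,
274,Radial/spiral veins I,systemic_vein,left,3,0.0124,0.0491,50,bed:3,
275,Ascending uterine vein I,systemic_vein,left,3,0.02405,0.048105,1,276;278,
276,Arcuate veins II,systemic_vein,left,12,0.0192,0.1963,4,277,
277,Radial/spiral veins II,systemic_vein,left,3,0.0124,0.0491,50,bed:4,
278,Ascending uterine vein II,systemic_vein,left,3,0.02405,0.048105,1,279;281,
279,Arcuate veins III,systemic_vein,left,12,0.0192,0.1963,4,280,
280,Radial/spiral veins III,systemic_vein,left,3,0.0124,0.0491,50,bed:5,
281,Ascending uterine vein III,systemic_vein,left,3,0.02405,0.048105,1,282;284,
282,Arcuate veins IV,systemic_vein,left,12,0.0192,0.1963,4,283,
283,Radial/spiral veins IV,systemic_vein,left,3,0.0124,0.0491,50,bed:6,
284,Ascending uterine vein IV,systemic_vein,left,3,0.02405,0.048105,1,273,
285,Descending uterine vein,systemic_vein,left,3,0.000314,0.001963,1,286,
286,Arcuate veins V,systemic_vein,left,12,0.0192,0.1963,4,287,
287,Radial/spiral veins V,systemic_vein,left,3,0.0124,0.0491,50,bed:7,
268,Uterine vein,systemic_vein,left,8,0.0767,0.7854,1,275;285;266,
266,Vaginal vein,systemic_vein,left,7,0.0098,0.02405,1,bed:7,
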